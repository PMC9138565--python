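"""End-to-end orchestration: structures in, report tables out.

A single :class:`RunConfig` drives the whole analysis: per-protein SASA
profiles, sequence descriptors, secondary-structure percentages,
nucleus/surface classification, SCR-SASA fingerprints with their
correlation matrix, and two Ward dendrograms (whole-protein summary
vectors and SCR fingerprints).  Every table written is re-derivable by
calling the underlying module function with the same config; a
provenance JSON echoes the config, seeds and package version.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chou_fasman import predict
from .environment import (
    EnvironmentSummary,
    ReferenceAccessibility,
    build_reference,
    classify,
    load_packaged_reference,
    summarize,
)
from .hier_clust import (
    euclidean_distances,
    similarity_percent,
    to_newick,
    ward_linkage,
)
from .scr_fingerprint import (
    correlation_matrix,
    fingerprint,
    identify_scrs,
    read_intervals,
    residue_preferences,
    scrs_from_intervals,
)
from .sasa_core import DEFAULT_N_POINTS, SASAProfile, sasa_profile
from .seqprops import AMINO_ACIDS, descriptors
from .structure_io import RadiiTable, read_fasta, read_pdb

logger = logging.getLogger("scrsasa")

__all__ = ["RunConfig", "run", "summary_vector", "SUMMARY_FEATURES"]

#: Whole-protein observation vector used for dendrogram clustering.
SUMMARY_FEATURES = (
    "TPS", "TAS", "TSA", "SCS", "BBS",
    "nucleus_total", "surface_total", "total_ave_sasa", "NAA",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all randomness seeded)."""

    pdbs: list[str] = field(default_factory=list)
    fasta: str | None = None
    alignment: str | None = None
    scr_intervals: str | None = None
    radii_file: str | None = None
    n_points: int = DEFAULT_N_POINTS
    reference: str = "packaged"  # or "regenerate"
    reference_n: int = 30
    reference_seed: int = 42
    nucleus_threshold: float = 0.2
    surface_threshold: float = 0.5
    scr_min_len: int = 5
    scr_min_conservation: float = 0.5
    fingerprint_component: str = "total"
    standardize: bool = False
    ave_denominator: str = "classified"
    out_dir: str = "scr-sasa-out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.nucleus_threshold < self.surface_threshold <= 1:
            raise ValueError("need 0 <= nucleus < surface <= 1 thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def summary_vector(
    profile: SASAProfile, summary: EnvironmentSummary
) -> np.ndarray:
    """9-component whole-protein observation (see SUMMARY_FEATURES)."""
    return np.array([
        profile.tps, profile.tas, profile.tsa, profile.scs, profile.bbs,
        summary.nucleus_total, summary.surface_total,
        summary.total_ave_sasa, float(len(profile.residues)),
    ])


def _standardize(vectors: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    mat = np.vstack(list(vectors.values()))
    mean = mat.mean(axis=0)
    std = mat.std(axis=0)
    std[std == 0] = 1.0
    return {k: (v - mean) / std for k, v in vectors.items()}


def _stage(name: str, count: int) -> None:
    logger.info("stage=%s inputs=%d", name, count)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the result bundle in memory.

    Writes the report tables (descriptor, composition, secondary
    structure, environment, fingerprint, correlation), two Newick trees
    and ``provenance.json`` into ``config.out_dir``.  Any stage failure
    aborts with the stage name and offending input in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    radii = (RadiiTable.from_yaml(config.radii_file)
             if config.radii_file else RadiiTable())

    if not config.pdbs:
        raise ValueError("stage=input: no PDB files configured")
    if not (config.alignment or config.scr_intervals):
        raise ValueError(
            "stage=input: no alignment and no SCR intervals configured; "
            "supply an aligned FASTA (alignment:) or an interval TSV "
            "(scr_intervals:)"
        )
    _stage("read_pdb", len(config.pdbs))
    structures = []
    for p in config.pdbs:
        try:
            structures.append(read_pdb(p, radii))
        except Exception as exc:
            raise RuntimeError(f"stage=read_pdb input={p}: {exc}") from exc

    _stage("sasa", len(structures))
    profiles: dict[str, SASAProfile] = {}
    for s in structures:
        profiles[s.id] = sasa_profile(s, radii, config.n_points)

    _stage("reference", 1)
    if config.reference == "packaged":
        ref: ReferenceAccessibility = load_packaged_reference()
    elif config.reference == "regenerate":
        ref = build_reference(config.reference_n, config.reference_seed,
                              radii, config.n_points)
    else:
        raise ValueError(f"stage=reference: unknown mode {config.reference!r}")

    _stage("classify", len(profiles))
    summaries: dict[str, EnvironmentSummary] = {}
    labels_by_protein = {}
    for pid, prof in profiles.items():
        labs = classify(prof, ref,
                        surface_threshold=config.surface_threshold,
                        nucleus_threshold=config.nucleus_threshold)
        labels_by_protein[pid] = labs
        summaries[pid] = summarize(prof, labs,
                                   denominator=config.ave_denominator)

    sequences = {s.id: s.sequence for s in structures}

    # ---- sequence-level tables -------------------------------------------
    _stage("descriptors", len(sequences))
    desc_rows, comp_rows, ss_rows = [], [], []
    for pid, seq in sequences.items():
        d = descriptors(seq)
        prof = profiles[pid]
        desc_rows.append({
            "protein": pid, "NAA": d.naa, "MW": round(d.mw, 2),
            "pI": round(d.pi, 2), "Asp + Glu": d.neg, "Arg + Lys": d.pos,
            "AI": round(d.ai, 2), "GRAVY": round(d.gravy, 3),
            "TPS": round(prof.tps, 2), "TAS": round(prof.tas, 2),
            "TSA": round(prof.tsa, 2), "SCS": round(prof.scs, 2),
            "BBS": round(prof.bbs, 2),
        })
        comp_rows.append({"protein": pid, "Length": d.naa,
                          **{aa: d.composition[aa] for aa in AMINO_ACIDS}})
        if len(seq) >= 6:
            ss = predict(seq)
            ss_rows.append({
                "protein": pid,
                "Helix (%)": round(ss.pct_helix, 1),
                "Sheet (%)": round(ss.pct_sheet, 1),
                "Turn (%)": round(ss.pct_turn, 1),
            })
    pd.DataFrame(desc_rows).to_csv(out / "descriptors.tsv", sep="\t", index=False)
    pd.DataFrame(comp_rows).to_csv(out / "composition.tsv", sep="\t", index=False)
    pd.DataFrame(ss_rows).to_csv(out / "secondary_structure.tsv", sep="\t",
                                 index=False)

    # ---- environment table (Total/Apolar/Backbone/Sidechain layout) ------
    env_rows = []
    for pid, summ in summaries.items():
        env_rows.append({"protein": pid, "SASA": "nucleus",
                         "Total": round(summ.nucleus_total, 2),
                         "Apolar": round(summ.nucleus_apolar, 2),
                         "Backbone": round(summ.nucleus_backbone, 2),
                         "Sidechain": round(summ.nucleus_sidechain, 2),
                         "Total Ave SASA": round(summ.total_ave_sasa, 2)})
        env_rows.append({"protein": pid, "SASA": "surface",
                         "Total": round(summ.surface_total, 2),
                         "Apolar": round(summ.surface_apolar, 2),
                         "Backbone": round(summ.surface_backbone, 2),
                         "Sidechain": round(summ.surface_sidechain, 2),
                         "Total Ave SASA": ""})
    pd.DataFrame(env_rows).to_csv(out / "environment.tsv", sep="\t", index=False)

    # ---- SCRs and fingerprints -------------------------------------------
    bundle: dict = {
        "profiles": profiles, "summaries": summaries,
        "labels": labels_by_protein, "reference": ref,
    }
    _stage("scr", len(sequences))
    if config.alignment:
        aln = read_fasta(config.alignment, alignment=True)
    else:
        aln = [(pid, sequences[pid]) for pid in profiles]
    if config.scr_intervals:
        scrs = scrs_from_intervals(aln, read_intervals(config.scr_intervals))
    else:
        scrs = identify_scrs(aln, config.scr_min_len,
                             config.scr_min_conservation)
    if not scrs.regions:
        raise RuntimeError("stage=scr: no conserved regions detected; "
                           "supply explicit intervals or relax thresholds")
    fingerprints = fingerprint(profiles, scrs,
                               component=config.fingerprint_component)
    fp_df = pd.DataFrame(
        {fp.protein_id: list(fp.values) for fp in fingerprints}
    )
    fp_df.to_csv(out / "fingerprints.tsv", sep="\t", index=False)
    labels_corr, corr = correlation_matrix(fingerprints)
    pd.DataFrame(np.round(corr, 2), index=labels_corr,
                 columns=labels_corr).to_csv(out / "correlation.tsv",
                                             sep="\t")
    prefs = residue_preferences(scrs, sequences)
    pd.DataFrame([prefs]).to_csv(out / "residue_preferences.tsv",
                                 sep="\t", index=False)
    bundle["scrs"] = scrs
    bundle["fingerprints"] = fingerprints

    # ---- clustering -------------------------------------------------------
    _stage("cluster", len(profiles))
    vectors = {
        pid: summary_vector(profiles[pid], summaries[pid]) for pid in profiles
    }
    if config.standardize:
        vectors = _standardize(vectors)
    whole_tree = ward_linkage(euclidean_distances(vectors))
    (out / "whole_protein.nwk").write_text(to_newick(whole_tree) + "\n")
    bundle["whole_tree"] = whole_tree
    bundle["whole_similarity"] = similarity_percent(whole_tree)

    fp_vectors = {
        fp.protein_id: np.asarray(fp.values) for fp in fingerprints
    }
    scr_tree = ward_linkage(euclidean_distances(fp_vectors))
    (out / "scr_sasa.nwk").write_text(to_newick(scr_tree) + "\n")
    bundle["scr_tree"] = scr_tree
    bundle["scr_similarity"] = similarity_percent(scr_tree)

    provenance = {
        "package": "scrsasa",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "reference": {"ensemble_size": ref.ensemble_size, "seed": ref.seed,
                      "radii": ref.radii_tag},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return bundle
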