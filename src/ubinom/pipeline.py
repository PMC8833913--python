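"""End-to-end orchestration: digest → map → unique → differential → nominate → survive.

The pipeline mirrors the analysis funnel of a ligase-restoration
substrate screen: condition-unique diGly peptidoforms are mapped to
proteins, intersected with the proteins downregulated upon restoration
and with a clinical tumor-up list, and the resulting candidate signature
is scored on a patient cohort and stratified for survival.  Every stage
count lands in a manifest that fully determines a rerun.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .differential import (
    CLINICAL_THRESHOLDS,
    PROTEIN_THRESHOLDS,
    RNA_THRESHOLDS,
    apply_thresholds,
    concordance_venn4,
    differential_test,
)
from .digest import Peptidoform, map_peptide_to_protein
from .nominate import load_candidate_fixture, nominate
from .simulate import StudyBundle, StudyConfig, generate_study
from .survival import (
    cox_hr,
    density_dichotomize,
    km_estimate,
    logrank_test,
    signature_score,
    trim_by_survival,
)
from .ubsets import interactor_overlap, unique_to_condition, venn_counts

__all__ = ["RunManifest", "run_pipeline", "emit_report"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    config_digest: str
    seed: int
    version: str
    counts: dict = field(default_factory=dict)
    survival_stats: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    @property
    def digest(self) -> str:
        """Hash of the deterministic payload (timings and paths excluded)."""
        payload = {
            "config_digest": self.config_digest,
            "seed": self.seed,
            "version": self.version,
            "counts": self.counts,
            "survival_stats": self.survival_stats,
            "recovery": self.recovery,
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _config_digest(config: StudyConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(
    config: StudyConfig | None = None,
    bundle: StudyBundle | None = None,
    out_dir=None,
    trim_k: int = 20,
) -> RunManifest:
    """Execute the full funnel on a simulated (or supplied) study bundle.

    Either *config* (simulate the study) or a prebuilt *bundle* must be
    given.  When *out_dir* is set, stage TSV/JSON outputs and the
    manifest are written there.
    """
    if bundle is None:
        if config is None:
            raise ValueError("provide a StudyConfig or a StudyBundle")
        bundle = generate_study(config)
    config = bundle.config
    manifest = RunManifest(
        config_digest=_config_digest(config),
        seed=config.seed,
        version=__version__,
    )
    counts = manifest.counts
    t0 = _time.perf_counter()

    # --- ubiquitome set logic (MG132-treated stratum; untreated is QC) ---
    treated = [e for e in bundle.events if e.mg132]
    ctrl_keys = {e.key for e in treated if e.condition == "Ctrl"}
    vhl_keys = {e.key for e in treated if e.condition == "VHL"}
    venn = venn_counts(ctrl_keys, vhl_keys)
    counts["peptides_ctrl_mg132"] = len(ctrl_keys)
    counts["peptides_vhl_mg132"] = len(vhl_keys)
    counts["peptides_shared"] = venn["shared"]
    counts["peptides_unique_vhl"] = venn["unique_b"]
    untreated = [e for e in bundle.events if not e.mg132]
    counts["peptides_ctrl_untreated"] = len(
        {e.key for e in untreated if e.condition == "Ctrl"}
    )
    counts["peptides_vhl_untreated"] = len(
        {e.key for e in untreated if e.condition == "VHL"}
    )

    unique_keys = unique_to_condition(bundle.events, "VHL", "Ctrl",
                                      require_mg132=True)
    manifest.stage_seconds["sets"] = _time.perf_counter() - t0

    # --- site mapping ---
    t0 = _time.perf_counter()
    annotations = {}
    for key in sorted(unique_keys):
        bare, _, pos = key.partition("|")
        mods = tuple(int(p) for p in pos.split(",")) if pos else ()
        annotations[key] = map_peptide_to_protein(
            Peptidoform(bare, mods), bundle.proteome
        )
    ub_proteins = set()
    for anns in annotations.values():
        ub_proteins.update(a.protein_id for a in anns)
    counts["proteins_ub_unique_vhl"] = len(ub_proteins)
    overlap = interactor_overlap(ub_proteins, bundle.interactors,
                                 universe_size=len(bundle.proteome))
    counts["interactor_overlap"] = overlap.n_overlap
    manifest.survival_stats["interactor_overlap_p"] = overlap.p_value
    manifest.stage_seconds["mapping"] = _time.perf_counter() - t0

    # --- differential omics ---
    t0 = _time.perf_counter()
    prot_res = differential_test(bundle.proteome_matrix, "Ctrl", "VHL")
    prot_up, prot_down = apply_thresholds(prot_res, PROTEIN_THRESHOLDS)
    rna_res = differential_test(bundle.rna_matrix, "Ctrl", "VHL")
    rna_up, rna_down = apply_thresholds(rna_res, RNA_THRESHOLDS)
    regions = concordance_venn4(rna_up, rna_down, prot_up, prot_down)
    counts["rna_up"], counts["rna_down"] = len(rna_up), len(rna_down)
    counts["protein_up"], counts["protein_down"] = len(prot_up), len(prot_down)
    counts["concordant_down"] = len(regions["concordant_down"])
    counts["protein_only_down"] = len(regions["protein_down_only"])

    clin_res = differential_test(bundle.clinical_matrix, "normal", "tumor")
    clin_up, _ = apply_thresholds(clin_res, CLINICAL_THRESHOLDS)
    clinical_up = (
        clin_res.loc[sorted(clin_up)]
        .reset_index()
        .rename(columns={"feature_id": "protein_id",
                         "log2fc": "clinical_log2fc",
                         "clinical_fdr": "clinical_adj_p"})
    )
    clinical_up = clinical_up.rename(columns={"fdr": "clinical_adj_p"})[
        ["protein_id", "clinical_log2fc", "clinical_adj_p"]
    ]
    counts["clinical_up"] = len(clinical_up)
    manifest.stage_seconds["differential"] = _time.perf_counter() - t0

    # --- nomination ---
    t0 = _time.perf_counter()
    site_map = {}
    for anns in annotations.values():
        for a in anns:
            site_map.setdefault(a.protein_id, []).append(a)
    table, down_and_ub = nominate(
        ub_proteins, prot_down, clinical_up,
        cell_stats=prot_res, site_map=site_map,
    )
    counts["down_and_ub"] = len(down_and_ub)
    counts["nominated"] = len(table)
    manifest.stage_seconds["nomination"] = _time.perf_counter() - t0

    # --- recovery vs ground truth ---
    truth = bundle.truth
    nominated = set(table["protein_id"])
    true_set = set(truth.substrates)
    tp = len(nominated & true_set)
    manifest.recovery = {
        "n_true_substrates": len(true_set),
        "true_positives": tp,
        "sensitivity": tp / len(true_set) if true_set else float("nan"),
        "false_discovery_proportion": (
            (len(nominated) - tp) / len(nominated) if nominated else 0.0
        ),
    }

    # --- signature scoring and survival ---
    t0 = _time.perf_counter()
    genes = sorted(nominated)
    if genes:
        scores = signature_score(bundle.patient_matrix, genes)
        threshold, labels, kde_info = density_dichotomize(scores)
        cohort = bundle.survival.copy()
        cohort["score"] = scores.loc[cohort["sample_id"]].to_numpy()
        cohort["stratum"] = pd.Series(labels, index=scores.index).loc[
            cohort["sample_id"]
        ].to_numpy()
        stat, logrank_p = logrank_test(cohort)
        cox_score = cox_hr(cohort["time"], cohort["event"], cohort["score"])
        cox_strat = cox_hr(cohort["time"], cohort["event"],
                           (cohort["stratum"] == "high").astype(float))
        k = min(trim_k, len(genes))
        trimmed = trim_by_survival(bundle.patient_matrix, cohort, genes, k=k)
        manifest.survival_stats.update(
            {
                "score_threshold": threshold,
                "kde": kde_info,
                "n_high": int((cohort["stratum"] == "high").sum()),
                "n_low": int((cohort["stratum"] == "low").sum()),
                "logrank_statistic": stat,
                "logrank_p": logrank_p,
                "cox_score_hr": cox_score.hr,
                "cox_score_coef": cox_score.coef,
                "cox_score_p": cox_score.p_value,
                "cox_stratum_hr": cox_strat.hr,
                "cox_stratum_p": cox_strat.p_value,
                "trimmed_signature": trimmed,
            }
        )
        counts["trimmed_signature"] = len(trimmed)
    else:
        logger.warning("no nominated candidates; survival stage skipped")
        cohort = None
    manifest.stage_seconds["survival"] = _time.perf_counter() - t0

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "candidates.tsv", sep="\t", index=False)
        pd.Series(sorted(down_and_ub)).to_csv(
            out / "down_and_ub.tsv", sep="\t", index=False, header=["protein_id"]
        )
        prot_res.to_csv(out / "proteome_differential.tsv", sep="\t")
        rna_res.to_csv(out / "rna_differential.tsv", sep="\t")
        clinical_up.to_csv(out / "clinical_up.tsv", sep="\t", index=False)
        if cohort is not None:
            cohort.to_csv(out / "cohort_strata.tsv", sep="\t", index=False)
            for label in ("high", "low"):
                km_estimate(cohort, label).to_csv(
                    out / f"km_{label}.tsv", sep="\t", index=False
                )
        (out / "manifest.json").write_text(manifest.to_json())
        manifest.outputs = {p.name: str(p) for p in sorted(out.iterdir())}
    return manifest


def run_fixture_nomination() -> RunManifest:
    """Validate and count the packaged clinical candidate table."""
    table = load_candidate_fixture()
    manifest = RunManifest(config_digest="fixture", seed=0, version=__version__)
    manifest.counts["nominated"] = len(table)
    manifest.counts["top_candidate"] = table.iloc[0]["protein_id"]
    return manifest


_FUNNEL = [
    "proteins_ub_unique_vhl",
    "down_and_ub",
    "nominated",
]


def emit_report(manifest: RunManifest) -> tuple[str, str]:
    """Render a manifest as a human-readable summary plus stable JSON.

    The JSON payload round-trips through :meth:`RunManifest.from_json`.
    """
    lines = ["# pipeline report", f"version {manifest.version}, seed {manifest.seed}"]
    lines.append("## funnel")
    for key in _FUNNEL:
        if key in manifest.counts:
            lines.append(f"  {key}: {manifest.counts[key]}")
    lines.append("## counts")
    for key, val in sorted(manifest.counts.items()):
        lines.append(f"  {key}: {val}")
    if manifest.survival_stats:
        lines.append("## survival")
        for key, val in sorted(manifest.survival_stats.items()):
            if isinstance(val, float):
                lines.append(f"  {key}: {val:.4g}")
            elif not isinstance(val, (dict, list)):
                lines.append(f"  {key}: {val}")
    if manifest.recovery:
        lines.append("## recovery")
        for key, val in sorted(manifest.recovery.items()):
            lines.append(f"  {key}: {val}")
    return "\n".join(lines), manifest.to_json()
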