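"""Substrate nomination: ubiquitinated ∩ downregulated ∩ tumor-up.

The headline integration of the pipeline.  A protein is nominated as a
putative E3-ligase substrate when it is (i) ubiquitinated only in the
ligase-restored condition, (ii) significantly downregulated at the
protein level in that condition, and (iii) overexpressed in tumors
relative to paired normal tissue in a clinical cohort.  A packaged
fixture carries the published 57-protein candidate table for validation
and for running the prognostic-signature stages without cohort access.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digest import SiteAnnotation

__all__ = [
    "nominate",
    "rank_candidates",
    "load_candidate_fixture",
    "validate_candidate_table",
    "CANDIDATE_COLUMNS",
]

CANDIDATE_COLUMNS = [
    "protein_id",
    "clinical_log2fc",
    "clinical_adj_p",
    "cell_log2fc",
    "cell_fdr",
    "ub_sites",
]

_RANK_KEYS = {
    "clinical_log2fc": False,  # descending
    "clinical_adj_p": True,  # ascending
    "cell_log2fc": False,
}


def nominate(
    ub_proteins: Iterable[str],
    proteome_down: Iterable[str],
    clinical_up: pd.DataFrame,
    cell_stats: pd.DataFrame | None = None,
    site_map: Mapping[str, Sequence[SiteAnnotation]] | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Triple intersection with provenance columns.

    *clinical_up* must have columns ``protein_id``, ``clinical_log2fc``,
    ``clinical_adj_p`` (one row per protein; duplicates raise).
    *cell_stats* is an optional differential-result frame (indexed by
    feature) supplying ``cell_log2fc``/``cell_fdr``; *site_map* maps
    protein IDs to their ubiquitination-site annotations.

    Returns ``(candidate_table, down_and_ub)`` where ``down_and_ub`` is
    the intermediate ubiquitinated-and-downregulated protein set, itself
    a first-class output.  The table is sorted by ``clinical_log2fc``
    descending, ties broken by protein ID.
    """
    ub = set(ub_proteins)
    down = set(proteome_down)
    dupes = clinical_up["protein_id"][clinical_up["protein_id"].duplicated()]
    if len(dupes):
        raise ValueError(
            f"duplicate protein IDs in clinical list: {sorted(set(dupes))}"
        )
    down_and_ub = ub & down
    clinical_ids = set(clinical_up["protein_id"])
    final = down_and_ub & clinical_ids
    rows = clinical_up[clinical_up["protein_id"].isin(final)].copy()
    if cell_stats is not None:
        rows["cell_log2fc"] = rows["protein_id"].map(cell_stats["log2fc"])
        rows["cell_fdr"] = rows["protein_id"].map(cell_stats["fdr"])
    else:
        rows["cell_log2fc"] = float("nan")
        rows["cell_fdr"] = float("nan")
    if site_map is not None:
        rows["ub_sites"] = rows["protein_id"].map(
            lambda pid: ";".join(
                f"K{pos}" for a in site_map.get(pid, ()) for pos in a.site_positions
            )
        )
    else:
        rows["ub_sites"] = ""
    table = rows[CANDIDATE_COLUMNS].reset_index(drop=True)
    return rank_candidates(table, "clinical_log2fc"), down_and_ub


def rank_candidates(table: pd.DataFrame, key: str = "clinical_log2fc") -> pd.DataFrame:
    """Stable sort of a candidate table by one ranking criterion.

    Descending for fold changes, ascending for p values; ties always
    broken lexicographically by protein ID.
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; choose from {sorted(_RANK_KEYS)}")
    ascending = _RANK_KEYS[key]
    return (
        table.sort_values(
            [key, "protein_id"], ascending=[ascending, True], kind="mergesort"
        )
        .reset_index(drop=True)
    )


def validate_candidate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check candidate-table invariants; raise listing offending rows.

    Enforced: required columns present, unique protein IDs, adjusted p in
    (0, 0.05).  The tumor-vs-normal fold-change bound (log2FC > 1) that
    defines the clinical up-list is documentation rather than an enforced
    invariant here: the published table itself ranks proteins whose
    printed log2FC falls below 1.
    """
    missing = {"protein_id", "clinical_log2fc", "clinical_adj_p"} - set(table.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    problems = []
    dupes = table["protein_id"][table["protein_id"].duplicated()]
    if len(dupes):
        problems.append(f"duplicate protein IDs: {sorted(set(dupes))}")
    bad_p = table[
        ~((table["clinical_adj_p"] > 0) & (table["clinical_adj_p"] < 0.05))
    ]
    if len(bad_p):
        problems.append(
            f"rows with adjusted p outside (0, 0.05): {sorted(bad_p['protein_id'])}"
        )
    if problems:
        raise ValueError("invalid candidate table: " + "; ".join(problems))
    return table


def load_candidate_fixture() -> pd.DataFrame:
    """Load the packaged 57-protein clinical candidate table.

    Proteins ubiquitinated and downregulated upon VHL restoration in
    786-O cells and upregulated in ccRCC tumors versus paired normal
    tissue, ranked by tumor/normal fold change.  Values are transcribed
    from the published table.
    """
    path = resources.files("ubinom").joinpath("data/cptac_candidates.tsv")
    with resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t")
    return validate_candidate_table(table)
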