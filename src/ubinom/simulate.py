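"""Seeded generator for a complete synthetic substrate-screen study.

Emulates the statistical structure of a VHL-restoration multi-omics
experiment: a two-condition cell-line study (Ctrl vs VHL) in which a set
of true substrate proteins is ubiquitinated essentially only when the
ligase is restored (with MG132 boosting detection), downregulated at the
protein level but not at the mRNA level, and overexpressed in tumors of
a paired clinical cohort whose survival hazard is tied to the substrate
signature score.  Ground truth is kept alongside every output so that
recovery and calibration can be measured.

Randomness: one global seed; each output stream draws from its own
``default_rng([stream_id, seed])`` substream, so adding a new output
never perturbs existing ones.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .digest import Peptidoform, ProteinRecord, render_peptidoform, write_fasta
from .differential import OmicsMatrix
from .ubsets import UbEvent

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "StudyBundle",
    "generate_proteome",
    "generate_study",
    "simulate_survival",
    "venn_target_sets",
]

_INTERIOR_AA = np.array(list("ACDEFGHILMNQSTVWY"))  # no K/R/P in segment bodies

# fixed substream ids (never renumber; append only)
_S_PROTEOME, _S_UB, _S_CELL, _S_CLINICAL, _S_SURVIVAL, _S_INTERACT = range(6)


@dataclass(frozen=True)
class StudyConfig:
    """Generating parameters of the synthetic study.

    Defaults are the study conditions the recovery suite runs under:
    30 substrates among 300 proteins, a 1.5 log2 protein-level
    downregulation upon ligase restoration with 4 replicates per
    condition and replicate noise of 0.25 log2 units, no mRNA effect for
    substrates (2.5 log2 units for the HIF-target genes, which move at
    both levels), an eight-fold MG132 detection boost, and a 200-patient
    cohort with a 1.5 log2 tumor overexpression and a log hazard ratio
    of 0.7 per unit signature score with 20% censoring.
    """

    n_proteins: int = 300
    n_true_substrates: int = 30
    n_hif_targets: int = 40
    protein_effect: float = 1.5
    rna_effect: float = 2.5
    reps_per_condition: int = 4
    noise_sd: float = 0.25
    ub_background_rate: float = 0.10
    ub_condition_noise: float = 0.0125
    mg132_boost: float = 8.0
    n_patients: int = 200
    tumor_effect: float = 1.5
    clinical_noise_sd: float = 1.0
    survival_beta: float = 0.7
    censor_rate: float = 0.2
    length_range: tuple[int, int] = (150, 450)
    interactor_substrate_fraction: float = 0.6
    n_interactors: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_substrates + self.n_hif_targets > self.n_proteins:
            raise ValueError("substrates + HIF targets exceed proteome size")
        for name in ("ub_background_rate", "ub_condition_noise", "censor_rate",
                     "interactor_substrate_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("protein_effect", "rna_effect", "tumor_effect",
                     "survival_beta"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.mg132_boost < 1:
            raise ValueError("mg132_boost must be >= 1")
        if self.reps_per_condition < 2:
            raise ValueError("need >= 2 replicates per condition")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery bookkeeping."""

    substrates: list[str]
    hif_targets: list[str]
    planted_sites: dict[str, int]  # protein -> 1-based K position
    patient_group: dict[str, str]  # patient -> '3p_loss' | 'intact'
    survival_beta: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class StudyBundle:
    """Everything the pipeline consumes, plus the ground truth."""

    config: StudyConfig
    proteome: list[ProteinRecord]
    events: list[UbEvent]
    proteome_matrix: OmicsMatrix
    rna_matrix: OmicsMatrix
    clinical_matrix: OmicsMatrix
    patient_matrix: pd.DataFrame
    survival: pd.DataFrame
    interactors: set[str]
    truth: GroundTruth

    def write(self, out_dir) -> dict[str, str]:
        """Write the bundle as the plain-text formats the modules read."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        def _save(name, fn):
            p = out / name
            fn(p)
            paths[name] = str(p)

        _save("proteome.fasta", lambda p: write_fasta(self.proteome, p))
        ev = pd.DataFrame(
            {
                "sample": [e.sample for e in self.events],
                "condition": [e.condition for e in self.events],
                "mg132": [int(e.mg132) for e in self.events],
                "peptidoform": [_key_to_dialect(e.key) for e in self.events],
            }
        )
        _save("peptidoforms.tsv",
              lambda p: ev.to_csv(p, sep="\t", index=False))
        for name, m in [
            ("proteome_matrix", self.proteome_matrix),
            ("rna_matrix", self.rna_matrix),
            ("clinical_matrix", self.clinical_matrix),
        ]:
            _save(f"{name}.tsv",
                  lambda p, m=m: m.values.to_csv(p, sep="\t", index_label="feature_id"))
            groups = pd.DataFrame(
                {"sample": list(m.values.columns),
                 "group": [m.group_of[s] for s in m.values.columns]}
            )
            _save(f"{name}_groups.tsv",
                  lambda p, g=groups: g.to_csv(p, sep="\t", index=False))
        _save("patient_matrix.tsv",
              lambda p: self.patient_matrix.to_csv(p, sep="\t",
                                                   index_label="feature_id"))
        _save("survival.tsv",
              lambda p: self.survival.to_csv(p, sep="\t", index=False))
        _save("interactors.tsv",
              lambda p: p.write_text("\n".join(sorted(self.interactors)) + "\n"))
        _save("ground_truth.json", lambda p: p.write_text(self.truth.to_json()))
        return paths


def _key_to_dialect(key: str) -> str:
    """Render a peptidoform identity key back to K[gg] notation."""
    if "|" not in key:
        return key
    bare, pos = key.split("|")
    mods = tuple(int(p) for p in pos.split(","))
    return render_peptidoform(Peptidoform(bare, mods), "gg")


def generate_proteome(
    n: int,
    length_range: tuple[int, int] = (150, 450),
    seed: int = 0,
) -> list[ProteinRecord]:
    """Random tryptic-friendly protein sequences, reproducible per seed.

    Sequences are built from cleavage segments of 6–18 residues ending
    in K or R (no P anywhere), so that peptides with up to one missed
    cleavage fall mostly in the 7–31 length band typical of tryptic
    diGly surveys.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    rng = np.random.default_rng([_S_PROTEOME, seed])
    records = []
    width = max(4, len(str(n)))
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq: list[str] = []
        while len(seq) < length:
            seg = int(rng.integers(6, 19))
            seg = min(seg, length - len(seq))
            body = rng.choice(_INTERIOR_AA, size=max(seg - 1, 1)).tolist()
            if len(seq) + seg < length:
                body.append("K" if rng.random() < 0.5 else "R")
            seq.extend(body[:seg])
        records.append(ProteinRecord(id=f"P{i + 1:0{width}d}", sequence="".join(seq)))
    return records


def _cut_positions(seq: str) -> list[int]:
    return [i for i in range(1, len(seq)) if seq[i - 1] in "KR" and seq[i] != "P"]


def _k_cut_positions(seq: str) -> list[int]:
    return [i for i in _cut_positions(seq) if seq[i - 1] == "K"]


def _blocked_peptidoform(seq: str, cuts: list[int], site: int) -> Peptidoform:
    """The tryptic peptidoform observed when K at *site* carries a diGly.

    The modified K is uncleavable, so the peptide spans from the cut
    before the site to the cut after it (one forced missed cleavage).
    """
    prev = max((c for c in cuts if c < site), default=0)
    nxt = min((c for c in cuts if c > site), default=len(seq))
    return Peptidoform(seq[prev:nxt], (site - prev,))


def generate_study(config: StudyConfig) -> StudyBundle:
    """Generate the full synthetic study bundle under *config*."""
    seed = config.seed
    proteome = generate_proteome(config.n_proteins, config.length_range, seed)
    by_id = {p.id: p for p in proteome}

    # substrates need an internal cleavable K to carry the planted site
    eligible = [p.id for p in proteome if _k_cut_positions(p.sequence)]
    if len(eligible) < config.n_true_substrates + config.n_hif_targets:
        raise ValueError("proteome too small/K-poor for requested truth sets")
    rng_ub = np.random.default_rng([_S_UB, seed])
    chosen = rng_ub.choice(eligible,
                           size=config.n_true_substrates + config.n_hif_targets,
                           replace=False)
    substrates = sorted(chosen[: config.n_true_substrates].tolist())
    hif_targets = sorted(chosen[config.n_true_substrates:].tolist())

    planted_sites = {}
    for pid in substrates:
        ks = _k_cut_positions(by_id[pid].sequence)
        planted_sites[pid] = int(ks[rng_ub.integers(len(ks))])

    events = _generate_ub_events(config, proteome, planted_sites, rng_ub)

    rng_cell = np.random.default_rng([_S_CELL, seed])
    proteome_matrix = _cell_matrix(
        config, proteome, rng_cell, baseline_mu=20.0,
        shifted={pid: -config.protein_effect for pid in substrates + hif_targets},
    )
    rna_matrix = _cell_matrix(
        config, proteome, rng_cell, baseline_mu=8.0,
        shifted={pid: -config.rna_effect for pid in hif_targets},
    )

    rng_clin = np.random.default_rng([_S_CLINICAL, seed])
    clinical_matrix = _clinical_matrix(config, proteome, rng_clin,
                                       substrates, hif_targets)

    rng_surv = np.random.default_rng([_S_SURVIVAL, seed])
    patient_matrix, survival, patient_group = _patient_cohort(
        config, proteome, rng_surv, substrates
    )

    rng_int = np.random.default_rng([_S_INTERACT, seed])
    n_sub_in = int(round(config.interactor_substrate_fraction
                         * min(config.n_true_substrates, config.n_interactors)))
    inter = set(rng_int.choice(substrates, size=n_sub_in, replace=False))
    decoy_pool = sorted(set(by_id) - set(substrates))
    n_decoys = min(config.n_interactors - n_sub_in, len(decoy_pool))
    inter |= set(rng_int.choice(decoy_pool, size=n_decoys, replace=False))

    truth = GroundTruth(
        substrates=substrates,
        hif_targets=hif_targets,
        planted_sites=planted_sites,
        patient_group=patient_group,
        survival_beta=config.survival_beta,
    )
    return StudyBundle(
        config=config,
        proteome=proteome,
        events=events,
        proteome_matrix=proteome_matrix,
        rna_matrix=rna_matrix,
        clinical_matrix=clinical_matrix,
        patient_matrix=patient_matrix,
        survival=survival,
        interactors=inter,
        truth=truth,
    )


def _generate_ub_events(config, proteome, planted_sites, rng) -> list:
    """Ubiquitination events per condition × MG132 stratum.

    Per K site, a background diGly peptide is detected in both
    conditions with probability ``ub_background_rate``, and in exactly
    one condition (detection stochasticity of label-free acquisition)
    with probability ``ub_condition_noise`` per condition.  Planted
    substrate sites appear only under VHL.  The MG132-off stratum is a
    1/mg132_boost subsample of the treated stratum, strictly smaller by
    construction.
    """
    rate, noise = config.ub_background_rate, config.ub_condition_noise
    treated: dict[str, set[str]] = {"Ctrl": set(), "VHL": set()}
    for prot in proteome:
        cuts = _cut_positions(prot.sequence)
        planted = planted_sites.get(prot.id)
        for site in _k_cut_positions(prot.sequence):
            if site == planted:
                continue
            r = rng.random()
            if r < rate:
                key = _blocked_peptidoform(prot.sequence, cuts, site).key
                treated["Ctrl"].add(key)
                treated["VHL"].add(key)
            elif r < rate + 2 * noise:
                key = _blocked_peptidoform(prot.sequence, cuts, site).key
                treated["Ctrl" if r < rate + noise else "VHL"].add(key)
        if planted is not None:
            treated["VHL"].add(
                _blocked_peptidoform(prot.sequence, cuts, planted).key
            )
    events = []
    for cond, keys in treated.items():
        keys = sorted(keys)
        for key in keys:
            events.append(UbEvent(key=key, condition=cond, mg132=True,
                                  sample=f"{cond}_mg1"))
        keep = rng.random(len(keys)) < 1.0 / config.mg132_boost
        if keep.all() and len(keys):
            keep[0] = False  # untreated stratum must stay strictly smaller
        for key, kp in zip(keys, keep):
            if kp:
                events.append(UbEvent(key=key, condition=cond, mg132=False,
                                      sample=f"{cond}_mg0"))
    return events


def _cell_matrix(config, proteome, rng, baseline_mu, shifted) -> OmicsMatrix:
    reps = config.reps_per_condition
    samples = [f"Ctrl_r{i + 1}" for i in range(reps)] + \
              [f"VHL_r{i + 1}" for i in range(reps)]
    groups = {s: s.split("_")[0] for s in samples}
    ids = [p.id for p in proteome]
    base = rng.normal(baseline_mu, 2.0, size=len(ids))
    vals = base[:, None] + rng.normal(0.0, config.noise_sd,
                                      size=(len(ids), 2 * reps))
    df = pd.DataFrame(vals, index=pd.Index(ids, name="feature_id"),
                      columns=samples)
    for pid, delta in shifted.items():
        df.loc[pid, df.columns[reps:]] += delta
    return OmicsMatrix(values=df, group_of=groups)


def _clinical_matrix(config, proteome, rng, substrates, hif_targets) -> OmicsMatrix:
    n = config.n_patients
    tumors = [f"T{i + 1:04d}" for i in range(n)]
    normals = [f"N{i + 1:04d}" for i in range(n)]
    groups = {**{s: "tumor" for s in tumors}, **{s: "normal" for s in normals}}
    ids = [p.id for p in proteome]
    base = rng.normal(6.0, 1.0, size=len(ids))
    vals = base[:, None] + rng.normal(0.0, config.clinical_noise_sd,
                                      size=(len(ids), 2 * n))
    df = pd.DataFrame(vals, index=pd.Index(ids, name="feature_id"),
                      columns=tumors + normals)
    for pid in substrates + hif_targets:
        df.loc[pid, tumors] += config.tumor_effect
    return OmicsMatrix(values=df, group_of=groups)


def _patient_cohort(config, proteome, rng, substrates):
    """Tumor-only expression matrix (log2-style, >= 0) plus survival.

    A latent copy-status group upshifts the substrate genes in ~60% of
    patients, which makes the substrate signature score bimodal; the
    event hazard is exponential in ``survival_beta`` per unit of
    (centered) signature score, with exponential censoring tuned to the
    requested censoring fraction.
    """
    n = config.n_patients
    patients = [f"PT{i + 1:04d}" for i in range(n)]
    ids = [p.id for p in proteome]
    base = rng.normal(6.0, 1.0, size=len(ids))
    vals = base[:, None] + rng.normal(0.0, 1.0, size=(len(ids), n))
    loss = rng.random(n) < 0.6
    df = pd.DataFrame(vals, index=pd.Index(ids, name="feature_id"),
                      columns=patients)
    df.loc[substrates, df.columns[loss]] += config.tumor_effect
    df = df.clip(lower=0.0)
    score = df.loc[substrates].mean(axis=0)
    time, event = simulate_survival(
        score.to_numpy() - float(score.mean()),
        beta=config.survival_beta,
        censor_rate=config.censor_rate,
        rng=rng,
    )
    survival = pd.DataFrame({"sample_id": patients, "time": time,
                             "event": event})
    patient_group = {p: ("3p_loss" if l else "intact")
                     for p, l in zip(patients, loss)}
    return df, survival, patient_group


def simulate_survival(
    covariate: Sequence[float],
    beta: float,
    censor_rate: float = 0.2,
    baseline_hazard: float = math.log(2) / 60.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Exponential survival with hazard ∝ exp(beta · covariate).

    Censoring is exponential with rate tuned so roughly *censor_rate* of
    subjects are censored at beta = 0.  Returns (time, event) arrays.
    """
    if rng is None:
        rng = np.random.default_rng([_S_SURVIVAL, 0 if seed is None else seed])
    x = np.asarray(covariate, dtype=float)
    lam = baseline_hazard * np.exp(beta * x)
    t_event = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(x))
    else:
        t_cens = np.full(len(x), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def venn_target_sets(
    n_a: int, n_b: int, n_unique_b: int, seed: int = 0
) -> tuple[set[str], set[str]]:
    """Two synthetic key sets realizing prescribed Venn totals.

    Useful for reproducing published two-set diagram arithmetic: given
    |A|, |B| and |B − A|, the shared count is |B| − |B − A| and the
    unique-to-A count is |A| − shared.
    """
    shared = n_b - n_unique_b
    unique_a = n_a - shared
    if shared < 0 or unique_a < 0:
        raise ValueError("inconsistent Venn totals")
    total = unique_a + shared + n_unique_b
    width = len(str(total))
    keys = [f"pep{i:0{width}d}" for i in range(total)]
    rng = np.random.default_rng([7, seed])
    rng.shuffle(keys)
    a = set(keys[: unique_a + shared])
    b = set(keys[unique_a : total])
    return a, b
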