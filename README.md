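# ubinom

**Ubiquitome-anchored nomination of E3-ubiquitin-ligase substrates, with
clinical prognostic scoring.**

When a substrate-recognition subunit such as VHL (the von Hippel–Lindau
tumor suppressor, lost in nearly all clear cell renal cell carcinoma) is
restored in a ligase-deficient cell line, its direct substrates become
ubiquitinated and degraded.  `ubinom` implements the computational side of
that screen as a reusable, tested pipeline:

1. **diGly site mapping** — parse modified-peptide strings carrying the
   K-ε-GG (diGly) ubiquitin remnant, simulate tryptic digestion (cleavage
   C-terminal to K/R, suppressed before P and at a modified K, which
   forces one missed cleavage), and map peptidoforms onto 1-based protein
   coordinates so a site can be reported as e.g. `K676`.
2. **Condition-unique calling** — peptidoforms observed under the
   restored condition and never in the control (within the
   MG132-treated stratum) are the candidate ubiquitination events; their
   proteins are tested against a curated interactor list with an
   upper-tail hypergeometric test.
3. **Differential filtering** — per-feature Welch *t* tests on log2
   matrices with Benjamini–Hochberg adjustment and strict threshold
   filters (transcripts: |FC| > 4, FDR < 0.01; proteins: |FC| > 1.5,
   FDR < 0.05; tumor vs normal: log2FC > 1, adjusted p < 0.05), plus the
   four-way mRNA/protein concordance partition that separates
   transcriptionally driven changes from protein-only (candidate
   post-translational) ones.
4. **Substrate nomination** — the triple intersection
   *ubiquitinated-unique ∩ proteome-down ∩ clinical-up*, ranked by
   tumor/normal fold change.  A packaged 57-protein candidate table (the
   published screen outcome, FTL at the top and including TGFBI and
   NFKB2) ships with the package.
5. **Prognostic scoring** — per-patient signature score as the geometric
   mean of the candidate genes' expression (computed in log2 space),
   dichotomized at the density minimum between the two dominant peaks of
   a Gaussian KDE (Silverman bandwidth; median fallback when unimodal),
   compared by Kaplan–Meier curves, the log-rank test and a
   single-covariate Cox proportional-hazards fit (Newton maximization of
   the partial likelihood, Breslow ties), and trimmed to the *k* = 20
   genes most associated with survival.
6. **Synthetic studies** — a seeded generator produces every input the
   pipeline consumes (proteome FASTA, peptidoform tables, omics
   matrices, paired clinical cohort, survival table, interactor list)
   with ground-truth bookkeeping, so sensitivity, false-discovery
   proportion and parameter recovery are measurable.

## Worked example

```python
import ubinom as u

# map a published diGly peptide onto its protein
proteome = u.read_fasta("src/ubinom/data/synthetic_tgfbi_nfkb2.fasta")
pf = u.parse_peptidoform("LAPVYQK[gg]LLER")
print(u.map_peptide_to_protein(pf, proteome)[0].site_positions)  # (676,)

# run the whole funnel on a synthetic study
manifest = u.run_pipeline(config=u.StudyConfig(seed=1))
print(manifest.counts["nominated"])            # 34
print(manifest.recovery["sensitivity"])        # 0.9666666666666667
print(round(manifest.survival_stats["logrank_statistic"], 3))  # 60.174
```

The study planted 30 true substrates among 300 proteins; the funnel
nominated 34 candidates of which 29 are true (sensitivity 0.967), and
the nominated signature separates the synthetic patients into strata
whose survival differs with a log-rank χ² of 60.2.  The same pipeline is
available from the shell:

```bash
ubinom run --seed 1 --out-dir out/          # full funnel + manifest.json
ubinom nominate --fixture --out table.tsv   # the packaged 57-row table
```

## Layout

- `src/ubinom/digest.py` — peptidoform parsing, tryptic digestion, site mapping
- `src/ubinom/ubsets.py` — condition-unique calls, Venn and hypergeometric overlap
- `src/ubinom/differential.py` — Welch/BH differential contract and threshold filters
- `src/ubinom/nominate.py` — triple-intersection nomination and the packaged table
- `src/ubinom/survival.py` — signature score, KDE dichotomization, KM/log-rank/Cox
- `src/ubinom/simulate.py` — seeded synthetic study generator with ground truth
- `src/ubinom/pipeline.py`, `src/ubinom/cli.py` — orchestration, manifest, CLI

See `docs/methods.md` for the modelling choices and their rationale.
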