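# cna-burden

Segmental aneuploidy from SNP-array copy number: independent-CNA calling and
counting, recurrent extreme-CNA region discovery, gene-level CNA frequencies,
and CNA-burden survival stratification — with a synthetic tumor-cohort
generator so every stage runs end to end with no external data.

## The problem

In superficial gastroesophageal adenocarcinoma (and many other solid tumors)
the degree of *segmental aneuploidy* — gain or loss of chromosome segments —
is a candidate prognostic biomarker. Given per-tumor segmented copy-number
profiles (tumor vs. matched normal on a high-density SNP array), the pipeline
quantifies aneuploidy per tumor, finds recurrently altered genomic regions,
and asks whether the aneuploidy burden stratifies survival. The association
is non-monotonic: tumors with *intermediate* burden carry the elevated
hazard, while the lowest and highest quartiles do comparatively well.

## The statistic

An **independent CNA** is a maximal run of contiguous segments whose copy
number lies strictly outside the diploid normal range [1.7, 2.3] and is
identical along the run; contiguous segments with *unequal* copy number are
separate events, so the **total CNA count**

&nbsp;&nbsp;&nbsp;&nbsp;N(tumor) = #{independent CNAs}

is essentially a breakpoint count. Downstream:

* **Extreme CNA**: copy number outside [1.474, 3.025] (the 10th/90th
  percentile of abnormal-segment copy number; fixed by default, recomputable
  in percentile mode).
* **Recurrent region**: an interval carrying extreme CNA of one direction in
  ≥ 3 distinct tumors (core), laterally extended through ≥ 2-tumor support.
* **Burden groups**: low = lowest quartile of N, high = highest quartile,
  intermediate = middle two quartiles (SPSS-style type-6 quartiles;
  boundary-inclusive ties). Groups are compared by Kaplan–Meier curves,
  the log-rank test, and Cox models of the intermediate-vs-rest indicator
  with univariate p < 0.2 covariate screening.

## Worked example

```python
import cnaburden as cb

cohort = cb.simulate_cohort(seed=1)            # default 41-tumor cohort
events = cb.call_cnas(cohort.segments)         # independent CNAs
counts = cb.count_per_sample(events)

groups = cb.assign_burden_groups(counts)
clinical = cb.simulate_clinical(groups.set_index("sample_id")["group"], seed=2)
os_tab = cb.prepare_survival(clinical, "os", burden=groups)
km = cb.km_logrank(os_tab)
cox = cb.cox_model(os_tab)
```

This prints (via the obvious `print` calls):

```
tumors: 41, events: 4812
total CNA count: min=12 median=83 max=432
burden groups: {'intermediate': 21, 'low': 10, 'high': 10}
OS analysis on n=39: log-rank p=0.050
intermediate-vs-rest HR=3.05 (95% CI 1.15-8.06)
```

Reading: the simulated cohort spans a ~35-fold range of CNA counts; quartile
grouping gives the 10/21/10 split; two perioperative deaths are excluded from
the overall-survival table (41 → 39); and the intermediate-burden group shows
the elevated death hazard that the generator plants (true HR 3.7 — a single
41-patient cohort estimates it with wide confidence limits).

The same chain is available from the shell:

```bash
cna-burden simulate --n-tumors 41 --seed 1 --out run/
cna-burden count run/truth_segments.seg --out-burden run/burden.csv
cna-burden recur run/truth_segments.seg --out run/regions.bed
cna-burden genes run/truth_segments.seg run/genes.bed --out run/genefreq.csv
cna-burden survival run/clinical.csv run/burden.csv --out run/survival.json
```

## Layout

| module | role |
|---|---|
| `cnaburden.io_formats` | SEG/BED/CSV/probe-TSV readers and writers; coordinate conventions |
| `cnaburden.synthetic_cohort` | cohort generator with ground truth (profiles, loci, outcomes) |
| `cnaburden.segmentation` | GC-bias correction; probe-level segmentation stand-in |
| `cnaburden.aneuploidy` | independent-CNA calling, total CNA count, burden summaries |
| `cnaburden.recurrence` | extreme thresholds, sweep-line recurrent regions, gene frequencies |
| `cnaburden.outcome` | burden groups, KM/log-rank, screened Cox, covariate tests |
| `cnaburden.cli` | `cna-burden` command-line chain |

See `docs/methods.md` for the model, parameter defaults, and limitations.
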