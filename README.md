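# mkpatterns

Classify LPS-responsive macrophage genes into MK2/MK3-dependent regulatory
patterns from single-channel microarray probe intensities.

The p38^MAPK downstream kinases MK2 and MK3 jointly and distinctly control
the transcriptional response of bone marrow-derived macrophages (BMDM) to
lipopolysaccharide (LPS). Given probe-level intensity matrices from
wild-type (wt), MK2-knockout (MK2KO) and MK2/3 double-knockout (MK23KO)
macrophages — untreated and after 2 h / 6 h of LPS, four replicates each —
this package:

1. floors intensities at 5, quantile-normalizes across all arrays,
   restricts to known-function probes, collapses each gene to the probe
   with the highest wt LPS induction, and normalizes to the untreated-wt
   mean;
2. calls LPS-responsive genes per genotype (pooled-variance Student's
   t-test against the untreated baseline, p < 0.05, no multiple-testing
   correction) and partitions responsive sets into three-way Venn regions;
3. keeps genes significantly wt-upregulated ≥ 4-fold that differ
   significantly in at least one pairwise genotype comparison
   ("MK2- and/or MK2/3-dependent"); and
4. allocates each such gene to one of six regulatory groups from the
   relation triple of its LPS-treated genotype means at a strict 20%
   threshold — rel(a,b) = GT/LT/EQ by (a−b)/b vs ±0.2:

   | group | exemplar | pattern |
   |---|---|---|
   | I | *Il10* | wt > MK2KO, MK23KO ≤ MK2KO |
   | II | *Il12b* | MK2KO > wt, MK23KO > wt |
   | III | *Ifnb1* | wt > MK2KO, MK23KO > MK2KO |
   | IV | *Cxcl3* | MK2KO > wt, MK23KO ≤ wt |
   | V | *Hdc* | wt ≈ MK2KO, MK23KO below both |
   | VI | *Cxcl9* | wt ≈ MK2KO, MK23KO above both |

A synthetic-data generator emulates the study design (planted regulatory
programs, multi-probe genes, per-array scale factors, log-normal noise) so
the whole pipeline is testable without external data. See
[docs/methods.md](docs/methods.md) for the model, parameters and known
limitations.

## Worked example

Run the numbered analysis scripts from the repository root:

```sh
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_responsiveness.py
python analysis/04_classify.py
python analysis/05_report.py
```

which prints (seed 7, default parameters):

```
simulated 5709 probes (3996 annotated to 2000 genes) x 36 arrays -> results/data/
5709 probes -> 2000 genes; values are ratios to the untreated wild-type mean -> results/gene_matrix.tsv
t=120 min: responsive of 2000 genes — wt 1565 (78%), MK2KO 1635 (82%), MK23KO 1568 (78%); union 1866; knockout-only 301
t=360 min: responsive of 2000 genes — wt 1602 (80%), MK2KO 1614 (81%), MK23KO 1576 (79%); union 1870; knockout-only 268
t=120 min: 343 wt-upregulated >=4-fold, 171 MK-dependent, 148 allocated (23 unclassified); group %: {'I': 34, 'II': 1, 'III': 32, 'IV': 0, 'V': 33, 'VI': 1}
t=360 min: 335 wt-upregulated >=4-fold, 183 MK-dependent, 151 allocated (32 unclassified); group %: {'I': 36, 'II': 0, 'III': 31, 'IV': 1, 'V': 29, 'VI': 3}
t=120 min: 144 filter-passing planted genes, 100.0% assigned their planted group
t=360 min: 144 filter-passing planted genes, 96.5% assigned their planted group
```

Reading the output: of 2,000 simulated genes, ~80% are called
LPS-responsive per genotype (the simulation plants large effects plus the
t-test's 5% false-positive rate; quantile normalization also shifts
unresponsive genes, see the methods note); 343 genes pass the wild-type
≥ 4-fold gate at 2 h, 171 of those differ significantly between genotypes,
and 148 receive one of the six patterns. Groups I, III and V dominate
because their planted wild-type induction (8×) survives the 4-fold gate
after quantile-normalization fold compression, while groups II, IV and VI
(planted exactly 4×) mostly do not — an instructive property of the
pipeline, discussed in the methods note. Every filter-passing planted gene
is assigned its true group at 2 h.

The same stages are scriptable via the CLI (`mkpatterns simulate |
preprocess | classify | report | run`) or the library API
(`mkpatterns.run_pipeline`), which writes gene matrices, responsiveness
calls, Venn summaries, assignments, heat-map/scatter tables and a run
manifest.

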