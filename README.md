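# circbench

Robustness benchmarking for back-splice-junction (circRNA) prediction from
total RNA-Seq.

Circular RNAs are detected from RNA-Seq through reads that span their
back-splice junction (BSJ) — the non-colinear join between a downstream
donor and an upstream acceptor. Predictions from a single total-RNA library
are unreliable: roughly half can fail validation. The standard truth signal
is an RNase-R-treated companion library (RNase R digests linear RNAs;
covalently closed circles survive). For a candidate with junction read count
*n* in the total-RNA library and *m* in the RNase-R library, the enrichment
score is

    E = (m − n) / (m + n),  E ∈ [−1, 1]

and a candidate is a **true positive** iff E > 0. The true-positive rate
(TPR) of a caller is n_true / n_predicted over all its total-RNA candidates
(after the standard ≥ 2 junction-read filter).

`circbench` packages the full evaluation workflow for people who study or
build circRNA callers:

* parsers for CIRI-style, KNIFE-style and BED-like prediction tables,
  normalized to strand-blind 1-based junction keys;
* the three "imperfect data" simulations — single-end projection, pair-level
  depth subsampling, and exact-k per-read base-error injection;
* enrichment labeling, TPR summaries, multi-caller combination at a support
  threshold, and top-k re-ranking by read count;
* per-circRNA properties (BSJ distance, E, junction-reads ratio R = n/N,
  read count) and a from-scratch two-sample Kolmogorov–Smirnov comparison of
  the circRNAs that survive degraded input (S1) against those lost (S2);
* a fully synthetic, ground-truthed benchmark — toy transcriptome, planted
  circles, RNase-R contrast, anchor-based pseudo-predictor with a decoy
  false-positive channel — so the entire pipeline runs with no downloads
  and no external callers.

See `docs/methods.md` for the models and their assumptions.

## Worked example

The published Hs68 fibroblast evaluation counts, through the same
`summarize()` arithmetic the benchmark uses
(`python analysis/04_reference_evaluation.py`):

```
CIRI1.2 : 1362/3488 true -> TPR 39.05%
CIRI2.0 : 1096/2207 true -> TPR 49.66%
KNIFE   : 1689/2854 true -> TPR 59.18%
```

The full synthetic study (`python analysis/02_degradation_response.py`,
default seed 42) prints:

```
baseline: 47 predicted, 37 true (TPR 78.72%)
  SE1   :   33 predicted,  23/37 true recovered (0.62)
  SE2   :   30 predicted,  20/37 true recovered (0.54)
  sub80 :   40 predicted,  30/37 true recovered (0.81)
  sub50 :   30 predicted,  20/37 true recovered (0.54)
  sub20 :   13 predicted,   3/37 true recovered (0.08)
  err2  :   47 predicted,  37/37 true recovered (1.00)
  err5  :   47 predicted,  37/37 true recovered (1.00)
  err10 :   41 predicted,  31/37 true recovered (0.84)
  err20 :   21 predicted,  10/37 true recovered (0.27)
```

Reading: of 47 candidates predicted from the perfect paired-end total-RNA
library, 37 are RNase-R enriched (the 10 others are decoy false positives —
all correctly labeled false). Recovery of true circles falls roughly in
proportion to depth (54% at half depth), collapses under heavy base errors,
and single-end input loses about a third of the true set.

The property comparison (`python analysis/03_property_separation.py`)
splits the 37 true circles into S1 = 20 still recovered at 50% depth and
S2 = 17 lost, and compares their property distributions:

```
property  n_S1  n_S2        D  p_value shift_direction
distance    20    17 0.252941 0.533945            left
       E    20    17 0.370588 0.122694            left
       R    20    17 0.555882 0.003748           right
   reads    20    17 0.591176 0.001646           right
```

Reading: junction read count and junction-reads ratio are significantly
right-shifted in the robust group — abundant, junction-dominated circRNAs
survive imperfect data — while the back-splice distance, which the generator
draws independently of expression, shows no significant shift.

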