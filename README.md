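# motifsel

Selection on RNA-binding-protein target motifs in coding sequences.

Coding sequences do more than encode protein: they must keep the short
k-mers through which RNA-binding proteins (RBPs) recognise the (pre-)mRNA,
and avoid gaining k-mers that would attract unwanted binding. `motifsel` is
a pipeline for quantifying both pressures from sequence data alone, for
molecular evolution researchers who want nucleotide-controlled answers to
three questions about a set of motifs:

1. **Enrichment** — is the motif set more (or less) frequent in CDSs than
   expected from its nucleotide composition?
2. **Conservation** — do motif-overlapping regions evolve more slowly at
   synonymous sites than composition predicts?
3. **Avoidance** — are substitutions that would *create* the motifs
   under-represented in evolution?

## The statistics

Every detector compares an observed statistic with its distribution over
*m* **simulant motif sets**: random sets matched to the real set in motif
number, motif lengths and (approximately) dinucleotide composition, built
by re-assembling the real set's two-phase dinucleotide pool. Results are
reported as a normalized statistic and an empirical P value:

```
ND            = (density − mean simulant density) / mean simulant density
normalized dS = (dS − mean simulant dS) / mean simulant dS
P             = (n + 1) / (m + 1)      n = # simulants at least as extreme
```

ND = 0 means chance frequency, 1 twice the expectation, −0.5 half; negative
normalized dS means excess conservation. The built-in synonymous-rate
estimator is Nei–Gojobori counting with Jukes–Cantor correction (an adapter
for PAML's `codeml` is available); noncoding regions use the Kimura
two-parameter distance. The avoidance test scores, at every 4-fold
degenerate site one substitution away from a motif, whether the orthologous
base is the one that would create it, weighted by how many of the three
substitutions would (0.75/0.5/0.25 for 1/2/3 creating bases).
`density × normalized rate × 100` estimates the percentage reduction in a
region's substitution rate attributable to motif preservation. Per-RBP
enrichment P values are tested for bimodality (enriched sets near 0,
avoided sets near 1) with an exact, self-contained implementation of
Hartigans' dip test. Genes are collapsed to paralogous-family units
throughout.

A first-class synthetic-data generator (`motifsel.simulate`) produces
background CDSs from a dinucleotide Markov model with valid ORF structure,
plants motif occurrences at controlled density multipliers, evolves
orthologs with distinct synonymous rates inside vs outside motif coverage
and optional suppression of motif-creating substitutions, and writes
expression tables — so the whole pipeline is testable against known ground
truth without any downloads.

## Worked example

Plant one enriched-and-conserved motif set and one depleted,
gain-suppressed set into 80 synthetic genes, then let the detectors find
them (runs in about half a minute):

```python
import numpy as np
from motifsel import (
    MotifSet, SimulationConfig, PlantedSet, simulate_study,
    generate_simulant_collection, set_enrichment, set_conservation,
    gain_statistics, global_reduction,
)
from motifsel.nulls import dinucleotide_pool, generate_simulant_set
from motifsel.catalog import parse_consensus

rng = np.random.default_rng(17)
base = MotifSet("ELAV-like", parse_consensus("UKWGDU") | parse_consensus("UUGCAU"))
pool = dinucleotide_pool(base)
kept = MotifSet("KEPT", generate_simulant_set(base, pool, rng=rng).motifs)
avoided = MotifSet("AVOIDED", generate_simulant_set(base, pool, rng=rng).motifs)

config = SimulationConfig(
    n_families=80, min_codons=300, max_codons=400, seed=17,
    planted=[
        PlantedSet(kept, multiplier=2.0, conserved=True),
        PlantedSet(avoided, multiplier=0.5, avoided=True),
    ],
    rate_motif=0.08, rate_background=0.16, gain_suppression=0.9,
)
data = simulate_study(config)

for mset in (kept, avoided):
    sims = generate_simulant_collection(mset, m=200, seed=17)
    enr = set_enrichment(data.records, mset, sims)
    print(f"{mset.rbp_id}: density={enr.raw_density:.4f}  ND={enr.nd:+.2f}  "
          f"P_enrich={enr.p_enrich:.3f}")
    if mset is kept:
        cons = set_conservation(data.pairs, mset, sims)
        print(f"       dS={cons.ds_raw:.4f}  normalized dS={cons.ds_norm:+.3f}  "
              f"P_cons={cons.p_cons:.3f}")
        print(f"       global reduction = "
              f"{global_reduction(enr.raw_density, cons.ds_norm):+.2f}%")
    else:
        gain = gain_statistics(data.pairs, mset, sims)
        print(f"       gain fraction={gain.weighted_fraction:.4f}  "
              f"normalized gain={gain.gain_norm:+.3f}  P_gain={gain.p_gain:.3f}")
```

Output:

```
KEPT: density=0.0577  ND=+0.85  P_enrich=0.005
       dS=0.0395  normalized dS=-0.364  P_cons=0.005
       global reduction = -2.10%
AVOIDED: density=0.0144  ND=-0.49  P_enrich=1.000
       gain fraction=0.0076  normalized gain=-0.767  P_gain=0.005
```

Reading it: the planted-for-keeping set is 1.85× as frequent as its
nucleotide-controlled expectation (ND +0.85) and beyond every one of the
200 simulant sets (P = 1/201 ≈ 0.005); its regions evolve 36% slower at
synonymous sites than composition predicts, an overall ~2.1% drag on the
synonymous rate. The avoided set is at half its expected frequency
(enrichment P = 1, i.e. significant depletion) and substitutions that would
create it are strongly under-accepted (normalized gain −0.77).

A `motifsel` command-line interface wraps the same pipeline for file-based
use: `motifsel catalog`, `simulants`, `scan`, `conserve`, `avoid`,
`summarize`, `simulate` (see `motifsel --help`).

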