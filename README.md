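# msavar

Per-column conservation/variability analysis of protein multiple sequence
alignments (MSAs), with mapping of dispersed structural residues
("functional compartments" — tunnels, gates, binding sites) onto alignment
columns and statistical comparison of their evolutionary rates against the
rest of the protein.

`msavar` is aimed at protein engineers and evolutionary analysts who have
an MSA of homologous sequences and, optionally, structural knowledge about
which residues line a tunnel or form a site, and who want to know: which
positions vary, which are preserved, and whether a structural compartment
evolves differently from the protein as a whole.

## What it computes

For each alignment column *i*, with `p_i` the amino-acid frequencies
(gaps included in the denominator) and `n_i` the number of distinct amino
acids (gaps excluded):

* **Shannon** entropy `H_i = −Σ_a q_a ln q_a` over gap-excluded frequencies
  `q` (nats);
* **Schneider** `H_i / ln 20 ∈ [0, 1]`;
* **Kabat** variability `k·N/n1` (distinct types × non-gap depth /
  majority-residue count);
* **E-score**, a normalised variability index built from the dominant
  residue frequency with gaps as a diluting extra letter:

  ```
  P_i = max(p_i) / n_i
  P_i^norm = P_i / max_j(P_j)
  E_i = −ln(P_i^norm) / max_j(−ln(P_j^norm))   ∈ [0, 1]
  ```

* **Landgraf** conservation: weighted asymmetric Gonnet-matrix distances
  `Σ_{j≠k} w_j (S(a_j,a_j) − S(a_j,a_k)) / (N(N−1))`;
* **RET** (real-valued Evolutionary Trace):
  `ρ_i = 1 + Σ_{n=1}^{N−1} (1/n) Σ_g H_{i,g}` over the groups `g` obtained
  by successive cuts of a UPGMA guide tree;
* **CRE** (cumulative relative entropy): `Σ_g (N_g/N) KL(p_g ‖ q)` of
  subgroup column distributions against the pooled distribution.

All metrics report *variability* orientation (higher = more variable).
Henikoff & Henikoff position-based sequence weights counteract taxonomic
bias, and BLOSUM62-derived pseudo-counts stabilise small alignments
(available for Kabat/Shannon/Schneider/E-score).  A "grouping mode"
re-expresses the alignment over a reduced property alphabet
(hydrophobicity classes etc.) before scoring.

Around the scores the package provides: consensus-sequence computation
with a minimum-frequency threshold, two outlier-detection routes
(consensus similarity and pairwise distances, Tukey-fence flagging),
compartment tables with numeric features, residue-numbering correction
from PDB REMARK 465 missing-residue records, residue→column mapping, the
two-sample Kolmogorov–Smirnov compartment-vs-rest test, per-position CSV
reports, and profile/composition/CDF/scatter plots.

## Worked example

```python
import numpy as np
from msavar import (Alignment, score_alignment, henikoff_weights,
                    consensus_sequence)

# four sequences, three columns: AAAA / AAA- / AACC (read column-wise)
a = Alignment(ids=("s1", "s2", "s3", "s4"),
              rows=("AAA", "AAA", "AAC", "A-C"))

for m in ("shannon", "schneider", "kabat", "escore"):
    print(m, np.round(score_alignment(a, m).values, 4))
print("henikoff", np.round(henikoff_weights(a), 4))
print("consensus", consensus_sequence(a, threshold=0.3).symbols)
```

prints

```
shannon [0.     0.     0.6931]
schneider [0.     0.     0.2314]
kabat [1. 1. 4.]
escore [0.     0.2075 1.    ]
henikoff [0.2222 0.2222 0.2222 0.3333]
consensus AAA
```

Column 1 is invariant: zero entropy, Kabat 1, E-score 0.  Column 2 is
invariant among residues but one quarter gapped, so the entropy family
still reports 0 while the E-score (0.2075) registers the gap dilution —
`P = 0.75/1`, normalised against the column extremes.  Column 3 splits
A/C evenly: Shannon `ln 2 = 0.6931`, Kabat `2·4/2 = 4`, and the maximal
E-score 1.  Sequence s4, which diverges from the other three, earns the
largest Henikoff weight (0.3333 vs 0.2222) — redundancy is down-weighted.
The consensus at threshold 0.3 is `AAA` (gaps can never win a column).

The same analysis from the shell:

```sh
msavar fixtures --outdir fx --seed 11          # synthetic bundle
msavar score --msa fx/msa.fasta --metrics shannon,escore,ret \
       --ref ref --compartment fx/compartment.tsv --pdb fx/structure.pdb \
       --out profile.csv
msavar compare --msa fx/msa.fasta --metric ret --ref ref \
       --compartment fx/compartment.tsv --pdb fx/structure.pdb --out ks.csv
```

`profile.csv` holds one row per alignment column (position, reference
residue number, consensus symbol, each metric, compartment flags and
features); `ks.csv` holds the KS statistic `D`, its asymptotic p-value and
the two sample sizes.

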