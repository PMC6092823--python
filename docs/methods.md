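# Methods

## Scope and data model

The package operates on a rectangular protein MSA over the 20 standard
amino acids, the gap `'-'` and `'X'`.  Non-standard letters (B, Z, J, U,
O, `*`) are mapped to `'X'` on ingest; `'X'` is excluded from amino-acid
counts but contributes to column totals like a gap, which keeps the
20-letter alphabet closed without silently dropping rows.  Columns are
1-based in all user-facing output; trimming retains the original column
indices as provenance so positions remain citable after editing.

## Column bookkeeping

For column *i*: `p_i` are amino-acid frequencies with gaps (and `'X'`) in
the denominator; `q_i` are gap-excluded frequencies; `n_i` is the number
of distinct amino acids present (gaps excluded).  All-gap columns are
degenerate: every metric reports NaN there, with a warning, and such
columns are excluded from the E-score normalisation maxima and from both
KS samples.

## The metrics

* **Shannon** `H = −Σ q ln q`, in nats.  Natural logarithms are used
  throughout; the normalised scores are base-invariant.
* **Schneider** `H / ln 20`.  The divisor is the fixed 20-letter maximum,
  not `ln min(20, N)`; with fewer sequences than residue types the score
  simply cannot reach 1, which is the expected small-sample caveat of this
  normalisation.
* **Kabat** `V = k·N/n1` with `k = n_i`, `N` the non-gap depth and `n1`
  the majority-residue count.  `V = 1` iff the column is invariant.
  Internally the ratio is computed as `k / max(q)`, which reduces to
  `k·N/n1` exactly and extends naturally to weighted or pseudo-corrected
  frequencies (where `k` remains the *observed* type count — letting
  pseudo-counts inflate `k` to 20 would make the score meaningless).
* **E-score** `P_i = max(p_i)/n_i`, `P^norm = P/max(P)`,
  `E = −ln(P^norm)/max(−ln(P^norm))`.  The maximum in `P_i` is taken over
  amino acids only, even in gap-dominated columns: gaps act as a diluting
  extra letter in the denominator without ever being the "dominating"
  symbol, so gap-heavy columns stay distinguishable while remaining on the
  same scale.  When every column has equal `P` (e.g. all invariant), all
  `−ln(P^norm)` vanish and `E ≡ 0`.
* **Landgraf** `L = Σ_{j≠k} w_j·d(a_j→a_k) / (N(N−1))` with the
  asymmetric distance `d(a→b) = S(a,a) − S(a,b)`; the bundled default `S`
  is the Gonnet-1992 (PAM250-scale) matrix shipped with biopython, and any
  NCBI-format square matrix can be substituted.  Gapped and `'X'` rows are
  excluded from the column's pair set; a column with fewer than two
  scorable residues reports 0 (no pair evidence of variability).
* **RET** `ρ_i = 1 + Σ_{n=1}^{N−1} (1/n) Σ_g H_{i,g}`: the guide tree is
  cut into `n` groups by splitting its `n−1` highest internal nodes, and
  `H_{i,g}` is the gap-excluded Shannon entropy of column *i* inside group
  *g* (groups without residues at the column contribute 0).  `ρ ≥ 1`,
  with equality iff every group at every level is column-invariant.
* **CRE** `Σ_g (N_g/N) Σ_a p_{a,g} ln(p_{a,g}/q_a)` with gap-excluded
  group and pooled frequencies; zero-frequency terms contribute 0, and a
  group with no residues at a column is skipped with a warning.  The
  default partition cuts the UPGMA tree at half its root height — a
  concrete, deterministic realisation of "subgroups defined by pairwise
  distances".

## Guide tree

UPGMA with arithmetic-mean linkage; node height is half the merge
distance, so the tree is ultrametric by construction.  Equal merge
distances are resolved by the lexicographically smallest pair of cluster
labels (each cluster labelled by its smallest member id), making the
topology deterministic.  This is implemented in-package rather than via
`scipy.cluster.hierarchy` because the tie-break is part of the contract
(RET partitions depend on it); the test suite cross-checks against both an
exhaustive-merge oracle and scipy's average linkage on matrices with
distinct entries.

## Weights and pseudo-counts

Henikoff position-based weights: raw weight `Σ_c 1/(k_c·n_{c,sym})` with
the gap (and `'X'`) counted as symbol types in `k_c`, normalised to sum
to 1.  When supplied to a score, weights replace counts with weight sums.

Pseudo-counts: `b_a = B·Σ_b f_b·g(a|b)`, `p'_a = (n_a + b_a)/(N + B)`,
applied to amino-acid counts only — gaps never receive pseudo-mass, and
the gap share of the E-score denominator is reinstated after adjustment.
Default `B = 5·n_i`, a standard choice for this scheme; the paper-style
background conditionals `g(a|b)` are derived at import time from the
BLOSUM62 log-odds matrix and its published background frequencies via
`q_ab ∝ p_a·p_b·2^(S_ab/2)`, row-normalised.  Any row-stochastic 20×20
plain-text table can be substituted.  Pseudo-counts are exposed for the
frequency-based scores (Kabat, Shannon, Schneider, E-score) only.

## Consensus and outliers

The consensus takes, per column, the (weighted) most frequent amino acid
if its frequency among *all* rows strictly exceeds the threshold (default
0.30, the common homology rule-of-thumb), else `'X'`; gaps sit in the
denominator but cannot win.  Ties break alphabetically and are flagged.

Outlier flagging uses Tukey fences at 1.5·IQR on (a) per-sequence
consensus similarity (low tail) and (b) mean pairwise distance (high
tail).  Quartiles are order statistics (nearest-rank); when the IQR is
zero the spread is degenerate and nothing is flagged.  The pairwise
distance is `1 − matches/comparable` where comparable columns are those
not gapped in both rows (gap against residue is a comparable mismatch); a
pair with no comparable columns scores 1 with a warning.  Flags are
advisory — removal/trimming is always the caller's decision, since
re-alignment may be required afterwards.

## Structure mapping

Compartment tables are whitespace-delimited text: residue number, residue
name (1- or 3-letter), optional numeric features (solvent exposure,
B-factors, MD fluctuation — any per-residue real).  Residue-name
mismatches against the reference sequence warn rather than fail; crystal
structures and database sequences legitimately differ.

Structure-derived residue numbers are often sequential over *observed*
residues, while sequences use author numbering.  `correct_numbering`
converts sequential→author using only the PDB REMARK 465 missing-residue
records (author numbering assumed contiguous from 1 apart from the missing
set): with missing {5, 6}, sequential index 5 becomes author residue 7.
The inverse is exposed; insertion codes are rejected because sequential
renumbering is ill-defined with them; coordinates are never read.
`build_residue_map` sends author residue *r* of the reference row to the
column of its *r*-th non-gap symbol.

## Compartment statistics

The two-sample KS test compares the metric's values on compartment
columns against the complement; `D = sup|ECDF₁ − ECDF₂|`, p-value from the
asymptotic Kolmogorov distribution with effective size `n₁n₂/(n₁+n₂)`
(scipy's `ks_2samp(method="asymp")`) — appropriate at the
hundreds-of-columns scale this analysis targets, and calibrated in the
test suite (type-I error within Monte-Carlo error of the nominal 0.05).
The 0.05 significance level appears only in reporting, never inside the
computation.  Extreme-position reports return the k least/most variable
columns honouring each metric's orientation flag, ties toward lower
column index.

## Synthetic data

The MSA generator draws each column independently: a random focal residue
and a Dirichlet-distributed residue distribution whose concentration on
the focal residue rises with the conservation level (`α_focal = α_other +
30c`, `α_other = 0.05 + 2(1−c)`); level 1 short-circuits to an exactly
invariant column.  Gap blocks gap a chosen fraction of rows across a
column range (emulating extra domains/large insertions); duplicate
clusters copy a source row with optional point substitutions (emulating
taxonomic bias).  Everything is reproducible bit-for-bit from (spec,
seed).

What the generator does *not* emulate: phylogenetic correlation between
columns or sequences, realistic substitution processes, indel evolution,
or alignment error.  Passing tests on this data therefore demonstrate the
correctness of the computations and their documented invariants — not
that any metric is a good estimator on real protein families.

The structure fixture emits a random reference protein, an alignment
embedding it (with an inserted gap block so columns ≠ residue numbers), a
compartment table in sequential numbering whose residue names are taken
from the reference, and a PDB fragment whose REMARK 465 lists exactly the
requested missing residues — so the correction→mapping round trip is
exact by construction and any regression breaks it loudly.

## Numerical choices and problem sizes

Frequencies are compared with absolute tolerances around 1e-12; consensus
tie detection uses 1e-12 on weighted frequencies.  CSV output renders
floats at 6 significant digits and leaves missing cells empty (no
sentinel text), so files round-trip value-for-value at that precision.
The acceptance pipeline uses a 40×200 synthetic study alignment, 500
replicates for KS null calibration, and 100-per-group samples — sizes
chosen to estimate the reported rates to within a few percent while
keeping the whole analysis interactive.

## Known limitations

* Landgraf's distance definition `d(a→b) = S(a,a) − S(a,b)` is this
  package's concrete reading of the substitution-matrix conservation
  index; other implementations differ in normalisation.
* Schneider can exceed intuition on reduced (grouping-mode) alphabets,
  since the `ln 20` divisor is kept for comparability across modes.
* The REMARK 465 correction assumes contiguous author numbering starting
  at 1; structures with negative or non-contiguous author numbering need
  pre-normalised tables.
* Asymptotic KS p-values are anti-conservative for very small compartments
  (< ~10 columns); sample sizes are reported so users can judge.
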