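# Methods

## Problem and model

Dicer excises a ~22-nt mature miRNA from one arm of a ~60–100 nt
pre-miRNA stem-loop; locating the 5′ mature start nucleotide inside
the hairpin is a needle-in-a-haystack classification problem: 1-nt
sliding over a hairpin of length L yields L − w + 1 candidate windows
of which exactly one starts at the annotated mature position, so the
positive:negative ratio is roughly 1:(L − w). `mirstart` treats this
explicitly as a class-imbalance problem and attacks it with two
coupled devices:

1. **Cluster-based undersampling.** All candidate windows of the
   annotated hairpins are encoded (below) and min-max normalized to
   [−1, 1]. The negatives are partitioned into k = 10 groups by
   seeded k-means (Euclidean distance), and each group contributes
   its ⌈n/k⌉ centroid-nearest members, trimmed globally to n = number
   of positives (ties broken by sample key). Together with all
   positives this forms the balanced round-1 subset S₁.

2. **AdaBoost-weighted RBF-SVM rounds with hard-example mining.**
   Boosting weights D are kept over the *full* window set of N
   samples, initialised uniform. Round m fits a soft-margin RBF-SVM
   (K(x, x′) = exp(−g‖x − x′‖²), 0 ≤ αᵢ ≤ C) on the current subset,
   is applied to all N windows, and receives

       e_m = Σ_i D_m(i) · [G_m(x_i) ≠ y_i]
       α_m = ½ ln((1 − e_m) / e_m)
       D_{m+1}(i) ∝ D_m(i) · exp(−α_m y_i G_m(x_i))   (renormalized)

   The samples round m misclassifies are unioned into S_{m+1}
   (deduplicated, so subset sizes are non-decreasing and every subset
   contains all positives). Training runs for at most M = 10 rounds
   and aborts — discarding the offending round — as soon as
   e_m ≥ ½; a perfect round (e_m = 0) is kept with its error clamped
   to 1/(2N) and ends the loop, since it contributes no new hard
   examples. At prediction time every window of a hairpin is scored
   by Σ_m α_m p_m(x), where p_m is round m's Platt-calibrated
   positive-class probability, and candidates are ranked descending
   (ties to the smaller start).

## Feature encoding (110 dimensions)

Each window is aligned against its pairing partner as a gapped
miRNA:miRNA* duplex read off the dot-bracket pair table: paired
anchors advance both strands, unpaired runs between anchors are
emitted left-justified with the shorter side padded by `-`, window
positions outside the anchored region face `-`, and the alignment is
truncated/right-padded with (N, N) columns to exactly 25 columns.
The vector then concatenates:

- `pn1–25`: the paired-nucleotide type of each column, an ordinal
  code over the 26 classes NN, AA, …, UU, -A, …, U-, --;
- `ss1–50`: per-column nucleotide + pair-state codes (10 classes
  N., A(, C(, G(, U(, A., C., G., U., -.), top strand then bottom;
- `fl1–18` / `fr1–6`: the same codes for the 9 hairpin positions
  immediately 5′ of the window and the 3 immediately 3′, with their
  partners; positions off the sequence end count as (N, unpaired);
- `MFE1–5`: nearest-neighbor stacking energy summed over adjacent
  paired columns of the whole duplex and of its left 3/5/9 and right
  3 columns (kcal/mol, always ≤ 0);
- `length`: distance from the window start to the first base of the
  terminal loop;
- `Num1–3`: gap counts over duplex columns 2–5, 3–8, 9–12;
- `fn`: the first window nucleotide (A=0…U=3);
- `pair`: 0 if the first duplex column is paired, else 1.

Both categorical codebooks are versioned bijections; persisted models
carry the codebook version and refuse to score under a different one.

The fl/fr blocks are read as the *flanking lower stem* (positions
outside the window) rather than duplex-internal columns, because
`ss1–50` already covers every duplex column; this is the only reading
that both sums to 110 and adds information. `MFE5` is computed over
the last three non-pad columns: real duplex alignments rarely reach
fixed columns 23–25, which would make a fixed-range feature
identically zero.

## Energy backend

Sub-region stability uses a packaged nearest-neighbor stack table
(`data/stack_energies.tsv`). The 16 Watson–Crick×Watson–Crick entries
are the standard Turner/Xia ΔG°₃₇ values; wobble-containing stacks
are conservative negative approximations, so region energy is
monotone non-increasing as the column range grows. Stacks are only
counted between *adjacent* paired columns — mismatches and bulges
interrupt a helix — and pairs missing from the table (non-canonical
"paired" columns in malformed external structures) contribute 0.
Users who want published minimum free energies can hook an external
folder via `--fold-cmd`; the built-in table keeps tests offline and
deterministic.

## SVM width and the (C, g) grid

Per round, (C, g) is chosen from a small grid by 3-fold
stratified-CV accuracy on the round's subset. The grid defaults to
C ∈ {2, 8} crossed with two widths: g = 0.5 and g = 1/110. The wide
exponent g = 0.5 is a published operating point for this feature
set, but on 110 min-max-normalized features squared distances
between samples concentrate around 20–160, where exp(−0.5 d²)
underflows: the kernel matrix degenerates to the identity, every
training sample becomes a support vector and the decision rule
collapses to its bias sign. The dimension-scaled width g = 1/110
(≈ the 1/n_features convention) keeps the kernel informative; the
cross-validated selection picks whichever width generalizes on the
data at hand, so the choice is data-driven rather than hard-coded.
All stochastic steps (k-means init, CV folds, Platt calibration)
draw per-use seeds from one user seed through a deterministic
stream.

## Baseline

The imbalanced-data baseline is a single RBF-SVM trained on the full
window set with the same grid search, ranking candidates by raw
decision value. Platt calibration is monotone in the decision value,
so per-hairpin rankings are unaffected, and skipping calibration
avoids a five-fold refit on the ~11k-row imbalanced matrix.

## Synthetic data

`mirstart.synth` generates hairpins as
flank5 + 5′arm + loop + 3′arm + flank3, the 3′ arm being the reverse
complement of the 5′ arm with per-position defects (mismatch, 5′
bulge, 3′ bulge) at rate `bulge_rate`; the dot-bracket structure is
emitted by construction, so every declared pair joins complementary
bases and no folding is needed. The annotated mature start is the
first 5′-arm base. With probability `signal_strength` the planted
signature is enforced: the first mature nucleotide is U and the
first 9 stem positions are defect-free. The signature is expressible
in the feature set itself (fn, pair, pn/fl codes), so learnability
exercises the encoder rather than a positional leak; flank, stem and
loop lengths are jittered per hairpin (±3, ±2, ±2 around the
configured values) so distance-to-loop is informative but absolute
position is not recoverable.

Defaults — 200 hairpins, flanks 8 nt, stem 30 nt, loop 8 nt, mature
22 nt, bulge rate 0.08, signal strength 0.9 — give ~84-nt hairpins
with ~63 candidate windows each (≈1:62 imbalance). The generator is
not a biological simulator: it matches neither miRBase base
composition nor multi-branch precursor structures, and hairpins with
the signature are more cleanly separable than real mature starts, so
passing recovery tests demonstrates that the pipeline learns a
signal expressible in its features — not field-realistic accuracy.

## Numerical and degenerate-input choices

- Min-max normalization maps constant features to 0 and clips test
  values into [−1, 1].
- Weight vectors are validated to sum to 1 within 1e−8 before use
  and renormalized exactly after each update.
- `round_alpha` is defined only on (0, 1); callers clamp e = 0.
- Ranking ties break toward the smaller start; grid ties toward the
  earlier grid entry; representative-selection ties toward the
  smaller sample key.
- A pair-free "hairpin" has no terminal loop; its distance-to-loop
  feature is 0 and its windows build all-gap duplexes.
- Windows may overlap the terminal loop; they become easy negatives.

## Problem sizes

Recovery experiments (tests and `scripts/acceptance.py`) use 200
hairpins (~180 train / 20 test, ~11k training windows), M = 10
rounds and the default grid; this trains in well under a minute on
one CPU. Smaller cohorts (12–60 hairpins) back the unit and CLI
tests.

## Known limitations

- 5′-arm mature starts only; no 3′-arm model.
- No pseudoknots; structures must be pseudoknot-free dot-bracket.
- The stacking table approximates wobble stacks; it is a feature
  backend, not a thermodynamics engine.
- Duplex alignments longer than 25 columns are truncated.
- Benchmarks against miRBase-trained predictors are out of scope;
  the package evaluates on its own synthetic cohorts.
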