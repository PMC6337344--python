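# Methods

## Model

An alignment of N sequences of length L over the 20 amino acids plus gap is
mapped to numeric vectors by an encoding: each amino acid becomes a length-s
real vector, the gap becomes the zero vector, and a sequence becomes the
concatenation X_n of its per-position vectors (length L·s).  The model
treats the X_n as independent draws from a multivariate Gaussian
N(μ, Σ); the maximum-likelihood estimates are the empirical mean X̄ and
covariance C̄.  Because sequences are phylogenetically related, both
moments are computed with per-sequence weights w(n) = 1/m_n, where m_n
counts the sequences (including n itself) sharing at least r·L identical
non-gap amino acids with sequence n; Meff = Σ w(n) is the effective number
of sequences.

C̄ is almost always rank-deficient (not every amino acid occurs at every
column), so it is blended with a prior derived from a uniform distribution
over the 20 amino-acid types.  With r̄ and Cr the mean and population
covariance of the 20 encoding vectors, the prior has mean μP (L copies of
r̄) and block-diagonal covariance CP (Cr on each position block, zero
elsewhere).  The corrected covariance is

    CM = λ·CP + (1−λ)·C̄ + λ(1−λ)·(X̄−μP)ᵀ(X̄−μP),   0 ≤ λ ≤ 1.

The coupling matrix is the precision matrix J = CM⁻¹; its off-diagonal s×s
blocks J(i,j) quantify the *conditional* dependence between columns i and
j, which is what separates direct couplings from correlations transmitted
through intermediate positions.

Each block is reduced to a scalar: the block is put in the zero-sum gauge
(subtract row means and column means, add the grand mean) and the score is
the sum of squared entries (squared Frobenius norm — any monotone
transform gives the same ranking).  The L×L score matrix receives the
average product correction, P_APC(i,j) = P(i,j) − rowsum(i)·colsum(j)/total,
and pairs with j − i > 4 are ranked by decreasing corrected score; the top
200 are the predicted contacts.

## Encodings

* **binary20** — amino acid i ↦ indicator vector e_i ∈ R²⁰.  Default
  λ = 0.8, the empirical optimum for this representation.
* **AAindex 1-D** — one real value per amino acid from an AAindex1 scale.
  The parser reads the H/D/I flat-file records (I values in
  ARNDCQEGHILKMFPSTWYV order over two lines); entries containing `NA` are
  flagged unusable, never imputed.  Values are used raw: the final ranking
  is invariant under any affine rescaling v ↦ a·v + b (a ≠ 0) of the
  scale, so standardization is cosmetic.  Default λ = 0.2.
* **BLOSUM-PCA** — each amino acid's row of a symmetric 20×20 substitution
  matrix is a point in R²⁰; points are column-centered and projected onto
  the top-k eigenvectors of their covariance (1/20 divisor; rankings are
  invariant to this global scale).  Coordinates are raw projections, not
  whitened.  Eigenvector signs are fixed by making each component's
  largest-magnitude loading positive, so the embedding is deterministic.
  Named BLOSUM matrices (45/50/62/80/90) load from Biopython; any matrix
  in the standard square text format is accepted from a file.  Default
  λ grows with k (≈0.5 at k=3, ≈0.73 at k=11, 0.8 at k=20), reflecting
  that larger covariance matrices are more under-sampled.

## Numerical choices

* **λ endpoints** are handled by explicit branches so that CM equals C̄ at
  λ=0 and CP at λ=1 bitwise, which makes the null-prior property (all
  inter-position couplings exactly zero at λ=1) exact rather than
  approximate.
* **Singularity and ridge.**  A gap-free alignment under binary20 is
  provably singular for every λ < 1 (each position block annihilates the
  all-ones direction, and the 20-type prior shares that null space).
  Inversion uses a Cholesky factorization with a ridge ladder: ε = 0
  first, then ε = 10⁻⁸·mean(diag(CM))·10^t for t = 0..6; the ε actually
  used is recorded in the model and in the run metadata.  If the ladder is
  exhausted a singular-model error suggests raising λ or allowing the
  ridge.
* **Score diagonal.**  P(i,i) is defined as 0 — a position is not a pair
  with itself — and the APC is evaluated over the full matrix including
  those zeros.  An option excludes entries with |i−j| ≤ d from the APC
  sums (off by default).  This convention makes the λ=1 null model produce
  exactly zero scores before *and* after APC.
* **Scalar couplings (s=1).**  Double-centering a 1×1 block is identically
  zero, so the gauge correction is degenerate for 1-D encodings; the score
  is then the plain squared coupling J(i,j)².  Affine invariance of the
  ranking is unaffected.
* **Ties** in ranking break lexicographically on (i, j); ties are
  measure-zero in float pipelines but common in degenerate inputs (e.g.
  the λ=1 null model), and the rule makes every ranking deterministic.
* **Identity counting** uses one BLAS product over a one-hot expansion
  (float32 accumulation is exact for counts ≤ L); gap–gap positions are
  not identities, and the diagonal of the identity matrix is 1 by
  convention so that each sequence is always its own neighbor.
* **Auto similarity cutoff** r = clip(0.32 / mean pairwise identity, 0.5,
  0.9).  Only the inverse proportionality is principled; the constant and
  the clip range are package choices, logged with every run, and the fixed
  mode (r = 0.8 by default) is the reproducible reference behavior.

## Synthetic alignments

The generator emulates the features the pipeline must cope with —
position-specific background composition, directly coupled column pairs,
gaps, and duplicated sequences — without simulating a phylogeny or a
substitution process.  Non-planted columns are i.i.d. from a background
distribution (uniform by default); for a planted pair, with probability
`coupling` the second residue is set equal to the first (a matched-type
pair table, P(a,a) = background(a)), otherwise drawn independently; gaps
are inserted i.i.d.; a `duplicate_rate` fraction of rows are exact copies
of earlier rows.  A chained preset plants i–j and j–k only, so the i–k
correlation is purely indirect — the case the precision matrix exists to
discount.  All draws come from one seeded generator stream.

Defaults are the package's study conditions: L = 60, N = 2000, 8 disjoint
planted pairs with separation > 4, coupling 0.8, gap rate 0.05, no
duplicates.  These are strong-signal conditions: passing recovery tests
shows the pipeline's machinery is correct end to end, not that real
families with weak, entangled couplings and non-i.i.d. gap structure would
be predicted equally well.  Affine-invariance checks use gap-free
alignments, because the gap vector is pinned at zero and is not carried
along by a transformation of the amino-acid values.

## Evaluation

A contact is a residue pair with minimum heavy-atom (non-hydrogen)
distance strictly below 8 Å.  PPV(k) is the fraction of the top-k
predictions that are true contacts; AUC200 = Σ_{k=1..200} PPV(k) (200 is
perfect).  When fewer than 200 predictions exist, only the available k are
summed and the result is flagged — no extrapolation.  Alignment columns
map to residues of the reference sequence (the alignment's first row) with
its gap columns excluded.  Two sets of per-family PPV curves are compared
with a two-tailed pooled-variance t-test at every k (Welch available);
they are declared different only if *every* per-k p-value is below 0.05.

## Known limitations

* The generator's pairwise coupling model produces no higher-order
  epistasis and no realistic gap correlation; Meff on synthetic data is
  near N unless duplicates are requested.
* The uniform prior is the only prior implemented; informative priors and
  sparse-inverse (graphical-lasso) estimation are out of scope.
* The PDB reader is deliberately minimal (ATOM records, first model,
  first chain); multi-chain complexes and author-numbered residue maps
  need a user-supplied contact list or mapping.
* Dense covariance storage bounds practical problem sizes to L·s of a few
  thousand (L ≈ 275 at s = 20 fits comfortably in desktop memory).
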