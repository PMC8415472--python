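# Methods

## Encoding

An aligned protein sequence over the 20 standard residues plus the gap
symbol is mapped, per property, to a number string x₁…x_L: residue letters
are replaced by the embedded measured value and gaps by exactly 0. Twelve
property columns are embedded (molecular mass, surface, volume, hydropathy
index, hydrophobicity, solubility, octanol–interface / octanol / interface
transfer free energies, pI at 25 °C, pKa of the α-NH₂ and α-COOH groups);
the constants are stored to the printed precision of their source
compilation and exported bit-identically as TSV. Input letters are
upper-cased and `.` is accepted as a gap synonym; any symbol outside the
21-letter alphabet (including B, J, O, U, X, Z and `*`) is rejected with
its position, since no measured values exist for ambiguity codes and
silently guessing would corrupt every downstream statistic.

The default property set for encoding, trees, correlation and AMI is
volume, hydropathy index, solubility, octanol–interface and pI at 25 °C;
the box-counting dimension defaults to volume, pI and solubility.
Hydrophobicity is excluded from the defaults because arginine's value is 0,
colliding with the gap code; note also that isoleucine and leucine share
volume (166.7 Å³) and molecular mass (131.175 Da), so those encodings are
not invertible either — only solubility, octanol and interface have 20
distinct nonzero values, and only for those can a number string be decoded
back to letters.

## Consensus and positional variability

Group consensus is strict per-column majority with gaps voting like
residues, so a mostly-gap column stays a gap (consensus alignments of real
protein families contain long gap stretches, and dropping them would shift
every downstream position index). Ties are resolved deterministically: a
residue beats the gap, and among tied residues the alphabetically first
wins. Positions are 1-based everywhere. Positional variability is the
per-column mean and sample (n−1) standard deviation across taxa; at least
two taxa are required.

## Trees

The tree distance is the sum-difference Σ|xᵢ − yᵢ| (L1). Construction is
agglomerative: find the pair of current profiles with the smallest
sum-difference, record that distance on the new internal node, replace the
pair by the position-wise arithmetic mean of the two profiles, repeat.
Averaging is deliberately unweighted at every merge — the two current
profiles are averaged regardless of cluster size (WPGMA-like, not
centroid-weighted). Equal minimal distances (essentially impossible with
real-valued strings, but reachable in degenerate input) break to the lowest
(row, column) pair in the current ordering.

For display the tree is laid out ultrametrically: a merge at distance d
sets the node height to d/2, and a child edge spans the height difference,
floored at 0 when merge distances are non-monotone (profile averaging can
bring a merged profile closer to a third taxon than its members were, so
monotonicity is not guaranteed). The raw merge distance is kept verbatim on
each node; a renderer that prefers to print the full distance on one edge
can therefore do so. Newick output round-trips through standard parsers.

Trees from a precomputed similarity matrix use 1 − r as the distance and
the same loop with WPGMA averaging of distances (there are no profiles to
average). Distance matrices read from labelled TSV or square PHYLIP text.

## Relatedness measures

*Correlation.* The lag-m autocorrelation of a single string is the
normalized lag-m autocovariance with the overall mean in both sums (the
1/N factors cancel); for two strings the lag-0 Pearson product-moment
correlation is used. Constant strings are an error rather than a NaN.

*Average mutual information.* Encoded values are treated as exact
categories (at most 21 distinct values per string, gap 0 included), not
binned: the strings are inherently categorical, and interval binning would
make the estimate depend on an arbitrary bin width. MI is the plug-in
H(X) + H(Y) − H(X,Y) in natural-log units by default, with a bits option.
No bias correction (Miller–Madow, shrinkage) is applied; with L ≳ 300
positions and ≤ 21 symbols the plug-in bias is small and identical across
pairs, which is what matters for relative comparisons.

*Box-counting dimension.* The scatter (xᵢ, yᵢ) is binned into a 10×10 grid
whose axes both span the common range [min of all values, max of all
values], half-open bins with the last closed; the dimension is
log(N_occupied)/log(10). The estimate is taken at this single scale, not by
multi-scale regression — the single-grid definition is the quantity of
interest here. A zero value range returns 0 with a warning. An optional
mode averages N_occupied over a 5×5 lattice of sub-cell grid offsets to
reduce quantization error from arbitrary grid placement; it is off by
default so that the plain single-grid number is reproducible.

*Aggregation.* Per taxon pair, a measure is computed once per property and
reported as mean ± sample (n−1) sd across properties, in an upper-triangle
matrix layout plus a machine-readable long format.

## Wavelets

The Morlet mother wavelet uses ω₀ = 6 (the community default; Fourier
period ≈ 1.033 × scale). Scales form a dyadic grid with 20 voices per
octave between Fourier periods 2 and 256 positions (clipped with a warning
when the signal is shorter). The transform is computed in the frequency
domain on the mean-centered, zero-padded series; the cone of influence is
the e-folding distance √2·s converted to period units, and all summary
statistics in the tests are restricted to cells inside it.

Coherence smoothing is a moving average over position with an odd window
of length ≈ 2× the scale (capped at the signal length) followed by a fixed
0.6-octave boxcar over scale, with the conventional 1/s weighting. Without
smoothing, coherence is identically 1 — a degeneracy the tests assert
against.

Significance is Monte-Carlo: surrogate pairs of white-noise series matched
to the two inputs' lengths, means and variances (an AR(1) option fits the
lag-1 autocorrelation instead; amino-acid property strings have no agreed
autoregressive null, so white noise is the default). A coherence cell is
locally significant at level 0.05 when the observed value exceeds the
per-cell 95% surrogate quantile; a period's average cross power is
significant at level 0.1 analogously. 100 surrogates by default; the
calibration checks use 200. All stochastic steps take an explicit seed
(default 1) and repeat runs with the same seed are bit-identical.

Phase classification follows the angular convention: in-phase on
(−π/2, π/2), out-of-phase on (π/2, π) ∪ (−π, −π/2); the boundary angles
fall in the out-of-phase class. The four rendered figures are the
average-power-versus-period curve with significance dots, the phase image
(in-phase and out-of-phase bands in distinct colormaps), the coherence heat
map with significance contours and phase arrows, and the cross-power heat
map; exact palettes are not a goal, band locations are.

## Synthetic families

The generator evolves a uniform-random root (uniform over the 20 residues,
no gaps) down a nested-pair topology, applying a configurable number of
substitutions per branch: positions drawn uniformly without replacement
outside protected blocks, replacement residues uniformly over the other 19.
Gap blocks are painted onto named leaves after evolution, fully masking the
underlying residues — gaps are assigned, not evolved, and there is no indel
model or rate heterogeneity beyond protected blocks. The model is
deliberately uniform rather than empirical (no exchangeability matrix):
these families exercise the analysis pipeline and make planted structure
checkable, but passing tests on them says nothing about fit to real
substitution processes, codon bias or alignment error.

Default study conditions used by the tests and the acceptance script:
356-position strings (the width of the real consensus alignments the
pipeline targets); four-taxon ((A,B),(C,D)) families with 5 within-pair and
60 cross-pair substitutions for topology recovery (100 families per
property); 50 descendant pairs per substitution level {0, 5, 20, 80} for
the correlation-degradation curve; white-noise type-I calibration at 200
surrogates averaged over a fixed set of independent pairs, since the
significant-cell fraction of a single realization is strongly spatially
correlated and fluctuates by several fold around the nominal level.

## Known limitations

- The relatedness measures ignore position order except through the
  wavelet and autocorrelation views; two alignments with permuted columns
  give identical MI and box dimension.
- The plug-in MI depends on the property through its value multiplicities
  (two residues sharing a value merge into one category).
- The box dimension at a single 10×10 scale saturates at 2 and is sensitive
  to outliers that stretch the common range.
- Wavelet significance is pointwise; no correction for testing many cells
  is applied, which is why the white-noise false-positive rate equals the
  nominal level rather than a family-wise one.
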