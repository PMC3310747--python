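# Methods

## Mass arithmetic

All masses are monoisotopic. The proton mass is taken as
H = 1.007276466 Da; every function accepts a `proton_mass` override, used
in tests and in the toy binning arguments where H = 1 Da keeps the
arithmetic legible (598 + 1 = 599 and so on). The charge-reduced ladder of
a precursor observed at m/z *p* under a hypothesised charge *c* is
computed from the implied neutral mass M = c·(p − H); the z = c element
reproduces *p* to machine precision, and `neutral_mass` / `mh` round-trip
exactly.

Peak lists are kept sorted by m/z; peaks with identical m/z are merged by
intensity summation at construction time, so downstream interval
arithmetic operates on a set, not a multiset.

## Precursor filter

Removal windows around each MH(z+), z = 1..n:

* variable-width variant (default): lower edge N1/z below the peak for
  z ≤ 2 (N1 = 60 Da, a blanket over all common losses including CO and
  the guanidino group), N2/z for z ≥ 3 (N2 = 18 Da, water); upper edge
  M/(W·z) above (W = 500), proportional to mass because the isotopic
  envelope of a heavy precursor is wide. Removal is applied only around
  the −17/−18 Da loss region for z ≥ 3, as specified by the window
  equations; losses of CO (−28 Da) and guanidino (−43 Da) from species
  with z ≥ 3 fall outside those windows and are deliberately not chased.
* fixed-width comparison variant: ±3.1 Da around each MH(z+) plus an
  N1/z neutral-loss window below it, for every z.
* passthrough.

Window membership is strict on both edges, exactly as the defining
inequalities are written: a peak at an exact boundary survives. With
floating-point data the distinction is almost immaterial, but the contract
is fixed and tested. When a spectrum carries a candidate charge *set*,
filtering uses the largest candidate: its windows cover every shared
reduced-precursor position of the smaller hypotheses, and conservative
removal is the design goal. Filtering a spectrum of unknown charge is an
error rather than a guess.

## Noise filter

Deisotoping removes peaks 1.0 ± 0.2 or 2.0 ± 0.2 Da *above* a more
intense retained peak, processing anchors in descending intensity order so
that a peak already removed as a satellite cannot itself remove others;
the most intense (monoisotopic) peak of a cluster is always retained.
Isotope spacing is treated as 1–2 Da only; 1/z spacings of multiply
charged species are left to the precursor filter's mass-proportional
windows, which is where those species are handled.

The sliding-window stage is peak-centred: each peak is retained iff it
ranks in the top h by intensity among all peaks within ±27 Da (1+ search,
h1) or ±14 Da (2+ search, h2) of itself. A fixed binning grid would make
retention depend on arbitrary bin phase, which the peak-centred reading of
"sliding window" avoids. Equal intensities rank the lower m/z first, for
determinism. Defaults are h1 = h2 = 2 (one forward series, one reverse
series); 3 is the recommended setting when c, z· and y ions are all
searched, and the retained set grows monotonically with h.

## Charge determination

For candidate charges 3..7 (configurable) two features per candidate are
extracted from the **raw** spectrum, each normalised by total ion current:

* CP: summed intensity in `(MH(z+) − tolp/z, MH(z+) + M/(W·z) + tolp/z)`,
  z = 1..c, with tolp = 2 Da and W = 500 shared with the precursor filter;
* NL: summed intensity in windows centred N2/z = 18/z below each MH(z+)
  with half-width tol/z = 4/z, covering both water and ammonia losses.

The feature vector fed to the classifier is one CP sum and one NL sum per
candidate (10 features for the 3..7 range). The per-candidate aggregation
keeps the discriminant well conditioned at a few hundred training spectra;
a per-z layout would multiply the dimensionality for no measured benefit
at that sample size. A CP-only mode exists to quantify what the NL
features add: they separate charge multiples (3+ vs 6+) whose CP bins
coincide.

The classifier is classic linear discriminant analysis: per-class means,
pooled within-class covariance (divisor N − K) ridged by
`1e-6 · trace(Σ)/d · I` to guarantee invertibility, priors defaulting to
empirical class frequencies, posteriors the softmax of the linear
discriminants. It is implemented directly (the fitted covariance, its
inverse and the ridge are part of the persisted plain-text model artifact,
and the posterior arithmetic is cross-checked in the tests against both an
explicit Gaussian-Bayes oracle and scikit-learn's LDA). Labels for
training normally come from the synthetic generator; `etdprep train`
equally accepts any externally supplied scan-id → charge table, e.g.
confident search-engine identifications.

Assignment strategies, with thresholds t1 = 0.99 and t2 = 0.9 on the best
posterior: Top 1 always emits one charge; Top 1/Top 2 emits the runner-up
too when the best posterior is below t1; 1/2/All emits the best charge
strictly above t1, the top two in [t2, t1], and the full candidate range
below t2. Boundary semantics follow the defining text ("greater than t1"
is strict; the middle band is inclusive); posterior ties prefer the lower
charge. Because the three candidate sets are nested, their
misclassification rates (true charge ∉ assigned set) are monotone by
construction.

## Pipeline order

Charge features are always extracted before any filtering: the precursor
filter deletes exactly the peaks the classifier reads. The pipeline
therefore runs charge assignment on the raw spectrum, then the precursor
filter with the assigned charge (largest candidate if several), then the
noise filter. The exported MGF contains the precursor-filtered,
deisotoped, ±27 Da/h1-thinned peak list; multi-candidate charges are
written in the `CHARGE=3+ and 4+` dialect.

## Synthetic spectra

The generator emulates the structure the method assumes, with per-peak
ground-truth labels (cp / nl / frag / noise):

* parent charge drawn from 20.1 / 51.4 / 19.4 / 7.7 / 1.4 % over 3+..7+,
  the charge breakdown of confidently identified ion-trap ETD
  phosphopeptide spectra, which is the default study condition everywhere;
* neutral mass from a uniform target of 330–850 Da of peptide per charge,
  clipped to 1000–6000 Da, realised as a random walk over the 20 standard
  residue masses (30 % of peptides get one +79.966 Da phospho on S/T/Y),
  so fragment positions are chemically plausible without any real
  sequence;
* reduced precursors at MH(z+), z = 1..n, lognormal intensity 10× the
  fragment scale, each with a mass-dependent isotope envelope of 1–4
  satellites at +k/z Da decaying by 0.6 per isotope — 1/z-spaced
  satellites are exactly what the deisotoper does *not* remove and the
  mass-proportional precursor windows do;
* ammonia and water losses at −17.027/z and −18.011/z with lognormal
  intensity 2× the fragment scale;
* c, z· and y ions (1+, plus 2+ above 1200 Da) with lognormal unit-scale
  intensity; 80 uniform noise peaks with exponential intensity
  (scale 0.5); every peak jittered by N(0, 0.1 Da).

Intensity laws are the simplest ones producing the qualitative dominance
of the reduced precursors; nothing downstream depends on their exact
shape. The generator does **not** model ETD fragmentation propensities,
hydrogen transfer (z vs z·), chimeric spectra, or profile-mode peak
shapes. Synthetic spectra are consequently cleaner than real ion-trap
data: the held-out misclassification of the 1/2/All strategy here is
essentially zero, where a few percent is realistic on instrument data, so
passing tests demonstrate correctness of the arithmetic and the expected
*ordering* of methods (NL features help on multiples; larger candidate
sets never hurt), not real-data error rates.

One consequence of point peaks plus jitter: a water-loss peak sits exactly
on the z ≥ 3 removal-window boundary, so roughly half of those (small)
peaks survive the precursor filter. On profile data the window covers most
of the loss peak's area; here it caps the removable CP+NL intensity at
about 97 %, which the filtering tests account for by asserting ≥ 95 %.

## Problem sizes and tolerances

The statistical tests run at desk scale, chosen once: 428 training
spectra (the size of a confident training set a single ion-trap
experiment yields), 2000 held-out spectra for error rates, 2000
3+/6+-only spectra for the multiples comparison, 10 000 draws for the
charge-distribution check (±1.5 percentage points, about three binomial
standard errors at the rarest class), and 1000 random spectra for the
brute-force oracle equivalence of both filters. All randomness flows from
fixed integer seeds; hypothesis profiles are derandomised.

## Known limitations

* Average (isotope-averaged) masses are unsupported; everything is
  monoisotopic.
* The deisotoper ignores 1/z isotope spacing by design (see above).
* High-resolution instrument behaviour is untested territory; the window
  defaults are ion-trap values.
* mzML/mzXML input is out of scope; MGF (and the annotated TSV sidecars)
  is the interchange format. The reader is a natural hook point for other
  formats.
* The product-ion-density feature sometimes used to call low charges in
  CAD data is intentionally absent; it does not improve this classifier.
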