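# Methods

## The question the package answers

Two communities can be equally "phylogenetically unique" on average for
opposite reasons.  One may sit on a long compositional gradient, so that its
dissimilarity to other sites grows steadily with distance (an *evolutionary
hill*: globally distinct, regionally ordinary).  The other may be abruptly
different even from its nearest neighbours, the signature of long-term
isolation (an *evolutionary island*).  Average uniqueness cannot separate
the two; the spatial scaling of uniqueness can.  This package computes the
required ingredients — an asymmetric phylogenetic dissimilarity index,
per-site distance-increase models, phylogenetic endemism, and
prioritisation curves — and classifies high-endemism sites as hills or
islands.

## Core quantities

**Branch sets and Faith's PD.**  A community's branch set is the union of
all edges on paths from its species' tips to the root of the full tree (the
*root-inclusive* convention); Faith's PD is the summed branch length of
that set.  A single-species community therefore spans its entire root path.
Root-inclusiveness is used consistently so that (i) deep branches shared by
two communities count as shared in pairwise comparisons and (ii) the
endemism values satisfy an exact conservation identity (below).  The main
alternative convention — PD of the re-rooted subtree spanning only the
listed tips — would break both properties and give a different value for
species-poor sites; users comparing against subtree-convention PD values
should expect discrepancies for small communities.

**Asymmetric dissimilarity.**  For a focal community F compared with
another community O,

    beta(F, O) = PD_unique / PD_total

where PD_total is F's branch-set length and PD_unique the length of the
part of F's branch set absent from O's.  The index is 0 when F's set nests
inside O's and 1 when the sets are disjoint, and it is asymmetric by
construction: beta(F, O) measures what is unique *to F*.  On a star tree
with equal tip branch lengths it reduces exactly to the species-level
proportion |F \ O| / |F|.  Pairwise values are held in a square matrix with
focal sites as rows; the row mean excluding the diagonal is the site's
*phylogenetic uniqueness*.  Computation uses a site-by-edge boolean
incidence matrix, so all n^2 pairs cost one matrix product; a streaming
row iterator is available when the full matrix would not fit in memory.
Values are clipped to [0, 1] after computation purely to absorb one-ulp
round-off (shared length can exceed PD_total by ~1e-16).

**Phylogenetic endemism.**  PE_i = sum over edges b in site i's branch set
of L_b / R_b, where L_b is the branch length and R_b the number of sites
whose branch set contains b.  Because each edge's contributions across
sites sum to exactly L_b, total PE equals the PD of the union of all
occupied sites — tested as an exact identity (relative tolerance 1e-9).

**Discrepancy analysis.**  PE and uniqueness are min-max standardised to
[0, 1] over the analysed sites (observed minimum and maximum, after the
richness filter), their difference taken per site, and regressed on
natural-log species richness by OLS.  The log base only rescales the slope,
not r².  A constant input vector degenerates the standardisation; the
affected variable is emitted as zeros with a warning.

## The distance-increase model

For each focal site, dissimilarities d to all other sites are modelled
against geodesic distance s (km) as

    d = 1 - a * exp(b * s)

equivalently expected similarity E[1 - d] = exp(log a + b s).  The fit is a
Gaussian-error, log-link GLM estimated by iteratively reweighted least
squares, with starting values from OLS on log similarity (similarities
clipped to >= 1e-10 for the initialisation only).  Plain Fisher scoring for
this family/link pair can oscillate indefinitely — the quadratic
approximation overshoots when mu is far from y — so each update is
step-halved until the deviance does not increase; convergence is a relative
deviance change below 1e-8 within 100 iterations.  Non-convergence is
flagged, never raised.  With exact exponential data the fit reproduces
(a, b) to machine precision, and on well-conditioned noisy data it agrees
with an independent nonlinear least-squares fit to ~1e-7.

Parameters and derived metrics:

| quantity | meaning | units |
|---|---|---|
| a | similarity of the fitted curve at s = 0 | dimensionless, >0 |
| b | exponential rate of similarity decay | per km, usually <= 0 |
| 1 - a (`dissimilarity_intercept`) | how dissimilar the site is even at zero distance | dimensionless |
| -b (`slope_metric`) | initial relative rate of dissimilarity increase | per km |
| pseudo r² | 1 - residual deviance / null deviance | dimensionless |

Both (a, b) and the derived pair are reported because the literature's
"intercept" and "slope" language refers to the *dissimilarity* curve while
the formula's a is a similarity-scale parameter; the classification uses
(1 - a, -b).  b is not constrained to be negative; a positive fit
(dissimilarity shrinking with distance) is legal and triggers a warning.
Pairs at zero distance (duplicate site centroids) are dropped per focal row
before fitting, since the log-link model cannot separate them from the
intercept.

## Distances

Site centroids are decimal-degree longitude/latitude.  The default
distance is the haversine great circle on the IUGG mean-radius sphere
(R = 6371.0088 km); one equatorial degree is 2*pi*R/360 = 111.19508 km and
the antipodal distance pi*R = 20015.11 km.  An ellipsoidal WGS84 option
(Vincenty's inverse formula with Lambert's approximation as the
near-antipodal fallback) differs from haversine by well under 0.6% and is
exposed behind a flag; the choice does not move any downstream quartile.
Distances are kept in km, so b is per km.

## Prioritisation curves

Sites are sorted in descending order of a per-site criterion (PE,
uniqueness, richness, PD, EDGE-score sum, EDGE richness), ties broken by
ascending site id for determinism.  The branch-set union is grown
incrementally and the PD of each prefix is recorded as a fraction of the
PD of the union of *all analysed sites* (i.e., after the richness filter),
one point per site.  Each prefix value is exact — equal to a from-scratch
PD of the accumulated species set — not an approximation.  These curves
rank simple per-site criteria; they are deliberately not a
complementarity-driven reserve-selection algorithm.

## Classification

Sites in the top quartile of PE (75th percentile, linear-interpolation
method; ties at the threshold included, so 25-100% of sites can flag) are
labelled by the scaling of their uniqueness: top-quartile `slope_metric`
-> *hill*, top-quartile `dissimilarity_intercept` -> *island*, both ->
*both*, otherwise *neither*.  Quartile thresholds for slope and intercept
are computed over all analysed sites by default; a switch restricts the
reference population to the top-PE sites, since either reading of the
procedure is defensible.  Unconverged fits are excluded from the quartile
computation and labelled neither.

Group contrasts between hills and islands (species richness, PE per
species, EDGE score per species) use the two-sided Wilcoxon rank-sum test
in its normal approximation with tie and continuity corrections
(`scipy.stats.mannwhitneyu`, asymptotic method) — appropriate because the
intended use case has hundreds to thousands of sites per group; no exact
small-sample enumeration is attempted, and groups smaller than two skip the
test with a warning.  Sites labelled *both* are excluded from the two
contrast groups by default.  Cross-taxon concordance counts, per site, how
many taxa flag it as top-PE (sites absent from a taxon count as unflagged)
and reports exact-count and at-least-count fractions.

## Synthetic landscapes

The generator emulates the structure of a gridded occurrence dataset
reconciled to a dated phylogeny, with planted ground truth:

* **Tree**: pure-birth (Yule) ultrametric tree, birth rate 1.0 per lineage
  per unit time, 200 tips by default; deterministic given the seed, tips
  relabelled `sp0001..`.
* **Sites**: a 10x10 lattice spanning 9 degrees (~1 degree = ~111 km
  spacing), 100 sites.
* **Ranges**: each species occupies all sites within a circular radius of
  a uniformly placed centre.  Radii grow from 2.2 deg at the western edge
  to 5.0 deg at the eastern edge.  The radii must span several lattice
  steps: if a radius is comparable to the site spacing, even adjacent
  sites share almost nothing and the zone plants isolation rather than a
  gradient.  At 2.2-5.0 deg, composition turns over gradually, faster in
  the west — the west third (minus islands) is the planted *hill* zone.
* **Islands**: 3 randomly placed sites each receive a private endemic
  clade.  The clade is the deepest (greatest total subtree branch length)
  unused clade with 8-16 tips — long-term isolation preserves an old,
  branch-rich lineage, and a shallow recent radiation would carry almost
  no endemism signal.  Each endemic tip is exclusive to its island with
  probability equal to the isolation strength (default 0.9), otherwise it
  also receives a normal mainland range; widespread species overlapping an
  island are excluded from it with the same probability.
* **Filter**: sites with fewer than 5 species are removed before analysis
  (the same minimum-richness rule the analysis applies to real data); a
  recipe whose islands cannot pass the filter raises a generation error.
* **Scores**: per-species conservation scores proportional to terminal
  branch length with lognormal noise (sd 0.35 on the log scale), top
  decile flagged — mimicking the rank structure of EDGE-style scores.

What the generator does *not* emulate: real range-shape complexity,
latitudinal richness gradients, climatic niches, dispersal barriers,
non-ultrametric trees, or observation error.  Passing tests therefore
demonstrate algorithmic correctness and recoverability of planted
structure under idealised spatial autocorrelation — not that any empirical
landscape will separate as cleanly.

Default problem sizes used throughout the test-suite and the
reproduction script (100 sites x 200 species, 10-20 replicate seeds;
oracle checks on trees of <= 12-14 tips; 100-200 replicate noisy fits of
500 pairs) were chosen so the whole suite completes in seconds while
keeping Monte-Carlo error well inside the asserted margins.

## Numerical choices and degenerate inputs

* Zero-length branches are allowed and contribute nothing; polytomies are
  accepted without binarisation; an unrooted basal trifurcation is treated
  as rooted at the basal node with a warning.
* A focal community of all-zero-length branches has no defined
  dissimilarity (PD_total = 0) and is rejected.
* All dissimilarities equal to 1 admit no log-link fit and raise a
  degenerate-fit error; `fit_all` records such rows as unconverged NaN
  fits instead of failing the batch.
* Output CSVs are written with 17 significant digits, so write-read
  round-trips are exact at double precision; every output carries the run
  seed as a leading `# seed=N` comment.
* All randomness flows from a single integer seed per run; reruns are
  byte-identical.

## Known limitations

* The n x n dissimilarity matrix is materialised by default (the streaming
  iterator avoids this but the CLI does not yet use it).
* The ellipsoidal distance path is O(n^2) Python-loop Vincenty; use
  haversine for large n.
* PE's branch range counts sites, not area; unequal-area site polygons
  would need external weighting.
* The hill/island split inherits the arbitrariness of quartile cutoffs;
  sites near a threshold can change label under resampling.
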