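# Methods

## Coordinates, alphabets, conventions

All internal coordinates are 0-based half-open (BED-native); 1-based formats
(VCF) are converted at the reader boundary. Bases are coded A=0, C=1, G=2,
T=3, with 4 for N or an alignment gap. N bases are excluded from every GC and
rate denominator. Repeat masking is carried as lowercase FASTA (an interval
track can be converted to the same per-base mask); window-level GC classes
use native GC, while the reference-GC stratification of large inter-barrier
regions uses masked GC with cut points 0.38 and 0.46.

**Border offsets.** Every analysis aligns sites on barrier borders. A site
inside a barrier gets offset −k where k is its distance-plus-one to the
*nearer* border (ties to the 5′ border); a site between two barriers gets
offset +k from the nearer border. Flank sites therefore never reach into a
neighbouring barrier and no site is counted twice. For strand-asymmetric
statistics (base changes, contexts), sites governed by a 5′ border are
reverse-complement mapped before pooling, so a G→A event left of a barrier
pools with C→T right of one. This is the symmetrization the profile figures
use; for scalar statistics (GC, tags) the mapping is a no-op.

## Barrier catalog and spacing

Catalogs are width-filtered to [36, 450] bp (the physical barrier predictions
above 450 bp show appreciable occupancy and are discarded). Interdistances
are border-to-border gaps between successive barriers; gaps containing an
unsequenced (N) run longer than 100 bp (configurable) are dropped. The
spacing tail is fitted by the maximum-likelihood mean of a truncated
exponential — by memorylessness, `mean(d − d_min)` — and the short-spacing
comb is found by maximizing the mean of the trend-normalized 1-bp histogram
over teeth `offset + k·period` (k = 0..4); the maximum is reported only when
its contrast exceeds both 0.15 and five counting standard errors of the
pooled tooth mass, so flat, exponential or sparse histograms return a null
result. Inter-barrier regions are assigned a nucleosome-count class
`n = round((d − 117)/153) + 1`, clipped to [1, 5], for d ≤ 800 bp; wider
regions are "fuzzy". The comb grid (offset 117 bp, period 153 bp) is adopted
as the class grid; the alternative of counting dyad peaks per region gives
the same bands on synthetic data but is noisier.

Coverage accounting splits the genome into three disjoint components:
barrier bp; bp of crystal-class (n ≤ 5) inter-barrier regions; and
2 × 270 bp of well-positioned flanking nucleosomes per large (d > 800 bp)
region. The 270-bp flank span is fixed by the exact integer identity
945,219 × 540 = 510,418,260 relating the genome-scale large-region count to
the printed flanking coverage; it is configurable. 100-kb window
stratification uses isochore GC classes (cuts 38/42/47/52 %), replication
timing classes (0.36/0.69), and either the fixed printed thresholds
(14.3/29.3 reads/kb; 0.378/1.681 cM/Mb) or 30/40/30 quantiles for DNase and
recombination. Crossover rates per window use the two most distant of ≥5
markers (cM difference over Mb); intergenes are gene-complement intervals
shrunk by 2 kb per gene-adjacent side.

## Occupancy Z-test

Per barrier, tags per mappable site are summarized inside (m₁, σ₁, n₁) and
over the two 300-bp flanks pooled (m₂, σ₂, n₂), flanks truncated at
neighbouring barriers and chromosome ends. SDs use the population form
(denominator n; at the n > 30 site minimum the n−1 form differs negligibly,
and the choice is fixed and documented). z = (m₂−m₁)/√(σ₁²/n₁+σ₂²/n₂);
z > 1.645 → G1 (depleted), z < −1.645 → G2, else G3; min(n₁,n₂) ≤ 30 →
excluded. Zero variance with equal means is conventionally G3.

**Calibration.** The 5 % per-side design size is exact under the normal CDF
and is recovered by Monte Carlo with iid normal per-site values (the
statistic's asymptotic regime) to within binomial error. With iid Poisson
counts at the study window sizes the realized size is measurably asymmetric —
about 0.053 (G1) / 0.048 (G2) at two tags per site, drifting toward
0.051/0.051 at high depth — the combined effect of the plug-in SDs
(a Welch-t with ≈235 df read against a normal threshold) and the Poisson
mean-variance coupling. This is a property of the test itself, not of the
implementation; group fractions from count data should be read with that
half-percent bias in mind.

Group comparisons elsewhere (GC, density, rates between region classes) use
the one-sided Welch unequal-variance test with the normal approximation to
the t distribution.

## Divergence, selection ratio, bootstrap

The ancestral base at a site is the base shared by chimpanzee, orangutan and
macaque (strict unanimity; a "chimp plus at least one outgroup" rule is
available). A site is *eligible* when the ancestral base is defined, the
human base is called, and both neighbouring columns are identical across all
four species; an *isolated substitution* is an eligible site where human
differs from ancestral. Eligible-site denominators enforce the same flank
criterion as events. Multiple substitutions are ignored by design (the
four-species divergence is small and two outgroups suppress most multiple
hits). CpG sites are flagged when three species carry an intact CG
dinucleotide and the fourth retains at least the relevant half (patterns
NG/CG/CG/CG, CG/NG/CG/CG, CN/CG/CG/CG, CG/CN/CG/CG); flagged sites are
excluded from C-ancestral rates and, because of reverse-complement pooling,
symmetrically from G-ancestral rates (configurable off). Equilibrium-GC
computations keep CpG sites.

Intraspecies events come from SNPs with minor allele frequency above 1 %:
the ancestral allele is the observed allele matching the reconstructed
ancestral base (chimp base as fallback); every other qualifying allele
contributes one polymorphism. SNP sites must satisfy the same eligibility
criterion as interspecies events so numerators and the shared denominator
count one site population.

Rates are `dInter(X→Y) = InterDiff/ancestralBase(X)` per offset (likewise
dIntra); 0/0 is undefined (NaN), never 0 or infinite, and undefined values
propagate. Background rates pool the central ±300 bp of inter-barrier
regions wider than 800 bp, where positioning is flat. The selection ratio
`S = (dInter/bgInter)/(dIntra/bgIntra)` is reported per change, per
reverse-complement pair, and for the pooled S→W / W→S classes (pooled pairs
share eligible sites, so the pooled rate sums the member-pair rates — the
highest-count classes and the ones used for detection).

The neutral null resamples the large-region centers: each of 10,000
replicates takes one uniformly random 10-bp window per large region, pools
counts, and forms S against the fixed backgrounds; the 2.5/97.5 percentiles
give the 95 % band and observed windowed S values get empirical tail
p-values without multiple-test correction (non-overlapping 10-bp windows are
independent draws). Replicates with undefined S (zero pooled intraspecies
count) are dropped from the percentiles.

Equilibrium GC treats the per-offset 4×4 rate matrix as a continuous-time
generator (off-diagonals = rates, rows sum to zero) and reports
π(G)+π(C) of its stationary vector, solved by least squares with the
normalization row; matrices of rank < 3 (reducible/degenerate) are
undefined. The one-step discrete chain has the same stationary vector at
these magnitudes, so only the generator form is implemented.

Context-dependent rates (e.g. tTt→tAt, sTs→sAs with s∈{c,g}, ¬aG¬a→¬aA¬a)
match the flanking bases of the *ancestral* sequence; at 5′-border sites the
reverse-complement context is matched instead. Context classes may overlap.

## Synthetic data

The generator defines the study conditions. Barriers: sequential placement
with exponential(1541 bp) border-to-border gaps (exactly the Poisson-spacing
signature) and truncated-gamma widths (shape 3, bounds [36, 450],
realized mean ≈155 bp). Composition: barrier GC 26.5 %, 300-bp flank GC
42.5 % with a damped cosine oscillation at the 153-bp repeat length,
background 37.9 %; poly(A)/poly(T) runs of 5–10 bp planted at the 5′/3′
barrier edges. Nucleosomes: an equilibrium one-dimensional hard-rod (Tonks)
gas of 147-bp footprints fills each inter-barrier region, with pressure set
by the target repeat length (mean gap 6 bp); the grand-canonical rod count
and uniform gap placement are sampled exactly, so the boundary-ordered,
damped-oscillatory dyad density (first peak near border + 74 bp, second one
repeat length further) is the true equilibrium profile rather than a
heuristic. This hard-rod gas is the package's own positioning model: it
reproduces the statistical-positioning phenomenology the analyses consume
(confinement ordering, repeat length, decay) without modelling
sequence-dependent bending energetics. Dyads are thinned to the requested
coverage (default 0.2 tags/bp) and a uniform leakage process at 0.15× the
nominal rate adds tags inside barriers, emulating the residual in-vitro
occupancy of predicted barriers. Divergence: the generated sequence is the
ancestral genome; outgroups are independent noisy copies at 0.2 %/site
(flank-identity filtering then retains >95 % of sites); the human copy
mutates with transition intensity 0.0032 and transversion intensity 0.0008
per site (≈0.5 % total, human-lineage scale), CpG C→T/G→A boosted 10×, and
optional position-dependent selection multipliers per change class
(inside/flank, inter/intra lineage). SNPs arise at unsubstituted sites at
≈0.4 %/site with derived-allele frequencies from Beta(0.4, 4), leaving a
substantial mass under the 1 % MAF cut to exercise the filter. Mappability
is an alternating exponential renewal process (3 % unmappable in 150-bp mean
gaps). All outputs are bit-exact functions of (truth, seed).

What the generator does **not** emulate: repeat families and their insertion
phasing (only a mask), neighbor-dependent substitution beyond CpG,
coalescent-accurate allele frequencies, recombination hotspot fine
structure, and real MNase digestion biases. Passing recovery tests therefore
demonstrate correctness of the estimators under the stated statistical
structure, not robustness to these real-data complications.

## Problem sizes and numerical choices

The neutral bootstrap-coverage study runs on 5 Mb (five 1-Mb chromosomes,
≈1,700–1,800 large inter-barrier regions) with the full 10,000 bootstrap
repetitions; coverage of the 95 % band is evaluated with 2,000 fresh draws
per change class from the same one-window-per-region law on an independent
RNG stream, giving the per-side exceedance with binomial error ≈0.0015.
The selection-recovery study runs on 40 Mb: at human-scale substitution
intensities a 10-bp bootstrap window needs tens of megabases of large
regions before the neutral band is narrower than the injected 1.5× effect,
and 40 Mb puts the pooled S→W band edge near 1.3 against an expected inside
signal of 1.5. Window pooling always sums counts before forming ratios
(never averages ratios). Smoothing is a count-weighted centered moving
average; even windows extend one extra base toward negative offsets.
Bootstrap gathers run in 500-replicate chunks (memory ≤ a few hundred MB at
40 Mb). Seeds: every stochastic entry point takes one integer seed;
internal stages derive independent streams from it via seed sequences, so
generation, bootstrap and evaluation draws never share a stream.

## Known limitations

- The Z-test inherits the paper-style plug-in-SD bias described above.
- The comb detector reports the best in-grid comb; a true period outside the
  configured grid is mis-assigned (flagged only by its lower contrast).
- Heat-map rows average width-ordered groups of 200 regions; the last,
  partial group is retained rather than dropped.
- The intergene/partition identity holds per chromosome only when merged
  genes do not abut chromosome ends.
- Multi-allelic SNP rows are handled per ALT row with the REF frequency
  computed from the summed ALT frequencies at the position.
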