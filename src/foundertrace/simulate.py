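"""Forward simulation of founder-haplotype descent and pipeline fixtures.

Everything the pipeline consumes can be generated here, seeded and
deterministic: marker genotypes of patients autozygous for a founder
variant (with the planted truth segment), genetic-map knot tables, binomial
carrier-screening draws, and the PCR-RFLP amplicon pair whose digestion
reproduces the assay's band patterns.

The descent model mirrors the dating estimator's assumptions exactly: each
of a patient's two lineages traces ``g`` meioses to the founder, the
retained ancestral flank on each side of the variant is Exponential(rate g)
in Morgans per lineage, and the autozygous segment is the intersection of
the two lineages' retained haplotypes (so each flank of the ROH is
Exponential(2g)).  Flank erosion is simulated directly on the genetic scale
and converted to physical coordinates through the (invertible) fixture map;
a slower meiosis-by-meiosis crossover simulator (Poisson crossovers per
meiosis) is provided as an independent cross-check path.

Inside the planted segment, markers are homozygous for the founder
haplotype's allele, which is drawn once per marker from its population
frequency — so patients sharing the founder are concordant at overlapping
ROH positions.  Outside, genotypes follow Hardy-Weinberg at the per-marker
frequencies.  An optional genotyping-error rate flips ROH calls to
heterozygous; an optional missing rate masks calls anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .freqstats import CohortCount
from .genmap import GeneticMap, PhysicalInterval, interpolate_cm
from .roh import AutozygousSegment, Call, MarkerGenotypes
from .rflp import HPY188III, PrimerPair, digest, find_sites

__all__ = [
    "SimulationConfig",
    "make_genetic_map_fixture",
    "inverse_interpolate_bp",
    "simulate_patient",
    "simulate_cohort",
    "simulate_segment_lengths",
    "simulate_cohort_counts",
    "make_rflp_fixture",
    "make_nonspecific_template",
    "ASSAY_PRIMERS",
]

#: the published Sanger/RFLP assay primers (forward / reverse, each 5'->3')
ASSAY_PRIMERS = PrimerPair(
    forward="GTGAGAGCCAAGTACCACAACA",
    reverse="GGAGAGTCACACATAAGTGGAGGT",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one founder-descent simulation.

    ``true_g`` is the number of generations (meioses per lineage) back to
    the founder; ``marker_freqs`` are per-marker population frequencies of
    the alternate allele (drawn Uniform(0.1, 0.9) when omitted, a typical
    informative-marker panel).
    """

    true_g: float = 10.0
    n_patients: int = 4
    chromosome: str = "chr9"
    chromosome_length_bp: int = 100_000_000
    marker_count: int = 5_000
    marker_spacing: Literal["uniform", "random"] = "random"
    marker_freqs: Optional[tuple[float, ...]] = None
    variant_position_bp: int = 50_000_000
    map_knots: int = 200
    mean_rate_cm_per_mb: float = 1.0
    het_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_g <= 0:
            raise ValueError("true_g must be positive")
        if not 1 <= self.variant_position_bp <= self.chromosome_length_bp:
            raise ValueError("variant_position_bp outside chromosome")
        if self.marker_freqs is not None:
            if len(self.marker_freqs) != self.marker_count:
                raise ValueError("marker_freqs must match marker_count")
            if any(not 0.0 <= f <= 1.0 for f in self.marker_freqs):
                raise ValueError("marker frequencies must lie in [0, 1]")
        for name in ("het_error_rate", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def make_genetic_map_fixture(
    chromosome_length_bp: int,
    knot_count: int,
    mean_rate_cm_per_mb: float = 1.0,
    seed: int = 0,
    chromosome: str = "chr9",
) -> GeneticMap:
    """A strictly increasing (hence invertible) synthetic genetic map.

    Knots span [1, chromosome_length_bp]; the local recombination rate of
    each inter-knot interval is lognormal around ``mean_rate_cm_per_mb``,
    so the map has realistic rate heterogeneity while staying strictly
    monotone.  With knot_count = 2 and a degenerate rate distribution the
    map is the identity-rate map (cm = bp / 1e6 * rate).
    """
    if chromosome_length_bp < 2 or knot_count < 2 or mean_rate_cm_per_mb <= 0:
        raise ValueError("arguments must be positive (length >= 2, knots >= 2)")
    rng = np.random.default_rng(seed)
    if knot_count == 2:
        bp = np.array([1, chromosome_length_bp], dtype=np.int64)
    else:
        interior = np.sort(
            rng.choice(
                np.arange(2, chromosome_length_bp, dtype=np.int64),
                size=knot_count - 2,
                replace=False,
            )
        )
        bp = np.concatenate([[1], interior, [chromosome_length_bp]])
    # lognormal local rates, mean-corrected to mean_rate_cm_per_mb
    sigma = 0.5 if knot_count > 2 else 0.0
    rates = mean_rate_cm_per_mb * rng.lognormal(-(sigma**2) / 2, sigma, bp.size - 1)
    cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(bp) / 1e6)])
    gmap = GeneticMap(build="synthetic")
    gmap.add_chromosome(chromosome, bp, cm)
    return gmap


def inverse_interpolate_bp(gmap: GeneticMap, chromosome: str, cm) -> np.ndarray:
    """Physical position(s) of genetic position(s): inverse of interpolate_cm.

    Requires a strictly increasing map (as the fixture generator produces);
    values beyond the map are clamped to the terminal knots.
    """
    kbp, kcm = gmap.knots[chromosome]
    if np.any(np.diff(kcm) <= 0):
        raise ValueError("map not strictly increasing; inverse is ill-defined")
    out = np.interp(np.asarray(cm, dtype=np.float64), kcm, kbp.astype(np.float64))
    return np.rint(out).astype(np.int64)


def _draw_flanks_cm(g: float, rng: np.random.Generator,
                    method: str) -> tuple[float, float]:
    """Left/right retained flank lengths (cM) of the autozygous segment."""
    if method == "exponential":
        # per lineage per side Exp(g) Morgans; intersection -> min of the two
        left = min(rng.exponential(1.0 / g), rng.exponential(1.0 / g))
        right = min(rng.exponential(1.0 / g), rng.exponential(1.0 / g))
        return left * 100.0, right * 100.0
    if method == "meiotic":
        # place Poisson crossovers meiosis by meiosis on a long genetic axis;
        # nearest crossover to the variant bounds the retained haplotype
        span_m = 50.0  # Morgans each side; far beyond any realistic flank
        flanks = np.full((2, 2), span_m)  # [lineage, side]
        for lineage in range(2):
            for _ in range(int(round(g))):
                n_x = rng.poisson(2 * span_m)
                if n_x:
                    xs = rng.uniform(-span_m, span_m, n_x)
                    left_xs = -xs[xs < 0]
                    right_xs = xs[xs > 0]
                    if left_xs.size:
                        flanks[lineage, 0] = min(flanks[lineage, 0], left_xs.min())
                    if right_xs.size:
                        flanks[lineage, 1] = min(flanks[lineage, 1], right_xs.min())
        left = min(flanks[0, 0], flanks[1, 0])
        right = min(flanks[0, 1], flanks[1, 1])
        return left * 100.0, right * 100.0
    raise ValueError(f"unknown descent method {method!r}")


def _founder_haplotype(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Marker positions, frequencies and the founder's allele at each marker.

    Derived deterministically from the config seed so every patient of one
    cohort shares the same marker panel and founder haplotype.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF00D]))
    L = config.chromosome_length_bp
    m = config.marker_count
    if config.marker_spacing == "uniform":
        positions = np.linspace(1, L, m).astype(np.int64)
    else:
        positions = np.sort(rng.choice(np.arange(1, L + 1), size=m, replace=False))
    if config.marker_freqs is not None:
        freqs = np.asarray(config.marker_freqs, dtype=np.float64)
    else:
        freqs = rng.uniform(0.1, 0.9, m)
    founder_allele = (rng.random(m) < freqs).astype(np.int8)  # 1 = ALT
    return positions, freqs, founder_allele


def simulate_patient(
    config: SimulationConfig,
    patient_index: int = 0,
    method: str = "exponential",
) -> tuple[MarkerGenotypes, AutozygousSegment]:
    """One autozygous patient: genotypes plus the planted truth segment."""
    positions, freqs, founder_allele = _founder_haplotype(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1, patient_index])
    )
    gmap = make_genetic_map_fixture(
        config.chromosome_length_bp, config.map_knots,
        config.mean_rate_cm_per_mb, seed=config.seed,
        chromosome=config.chromosome,
    )
    v_cm = interpolate_cm(gmap, config.chromosome, config.variant_position_bp)
    left_cm, right_cm = _draw_flanks_cm(config.true_g, rng, method)
    lo_cm = max(v_cm - left_cm, 0.0)
    hi_cm = v_cm + right_cm
    lo_bp, hi_bp = inverse_interpolate_bp(
        gmap, config.chromosome, [lo_cm, hi_cm]
    )
    lo_bp = int(max(lo_bp, 1))
    hi_bp = int(min(hi_bp, config.chromosome_length_bp))

    inside = (positions >= lo_bp) & (positions <= hi_bp)
    calls = np.empty(positions.size, dtype=np.int8)
    # Hardy-Weinberg outside the segment: 0/1/2 ALT alleles
    dosage = rng.binomial(2, freqs)
    calls[:] = np.where(dosage == 0, Call.HOM_REF,
                        np.where(dosage == 1, Call.HET, Call.HOM_ALT))
    calls[inside] = np.where(
        founder_allele[inside] == 1, Call.HOM_ALT, Call.HOM_REF
    )
    if config.het_error_rate > 0:
        flip = inside & (rng.random(positions.size) < config.het_error_rate)
        calls[flip] = Call.HET
    if config.missing_rate > 0:
        calls[rng.random(positions.size) < config.missing_rate] = Call.MISSING

    sample_id = f"sim{patient_index}"
    genotypes = MarkerGenotypes(
        chromosome=config.chromosome,
        positions=positions,
        calls=calls,
        sample_id=sample_id,
    )
    n_inside = int(inside.sum())
    truth = AutozygousSegment(
        chromosome=config.chromosome,
        start_bp=lo_bp,
        end_bp=hi_bp,
        n_markers=n_inside,
        n_het_inside=0,
        sample_id=sample_id,
    )
    return genotypes, truth


def simulate_cohort(
    config: SimulationConfig, method: str = "exponential"
) -> list[tuple[MarkerGenotypes, AutozygousSegment]]:
    """All ``config.n_patients`` patients, sharing the founder haplotype."""
    return [
        simulate_patient(config, i, method) for i in range(config.n_patients)
    ]


def simulate_segment_lengths(
    g: float, n_patients: int, seed: int = 0, method: str = "exponential"
) -> np.ndarray:
    """ROH genetic lengths (cM) only — the fast path for estimator studies."""
    rng = np.random.default_rng(seed)
    if method == "exponential":
        flanks = rng.exponential(1.0 / (2.0 * g), size=(n_patients, 2))
        return flanks.sum(axis=1) * 100.0
    return np.array([
        sum(_draw_flanks_cm(g, rng, method)) for _ in range(n_patients)
    ])


def simulate_cohort_counts(
    q: float, n_individuals: int, seed: int = 0,
    population_label: str = "simulated", ploidy: int = 2,
) -> CohortCount:
    """Binomial carrier-allele draw at allele frequency ``q``."""
    if not 0.0 <= q <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    x = int(rng.binomial(ploidy * n_individuals, q))
    return CohortCount(
        population_label=population_label,
        n_individuals=n_individuals,
        n_carrier_alleles=x,
        ploidy=ploidy,
    )


# -- RFLP fixture -------------------------------------------------------------

_AMPLICON_LEN = 357
_WT_SITE = 187   # cut at 187 + 2 = 189 -> fragments 189 + 168
_MUT_SITE = 120  # cut at 120 + 2 = 122 -> splits 189 into 122 + 67


def _repair_sites(seq: list[str], keep_starts: set[int],
                  protected: set[int]) -> None:
    """Destroy every recognition site not in keep_starts by mutating one base."""
    for _ in range(100):
        cuts = find_sites("".join(seq), HPY188III)
        spurious = [c - HPY188III.cut_offset for c in cuts
                    if c - HPY188III.cut_offset not in keep_starts]
        if not spurious:
            return
        for start in spurious:
            for pos in (start, start + 1, start + 4, start + 5):  # T,C,G,A of TCNNGA
                if pos not in protected and 0 <= pos < len(seq):
                    seq[pos] = {"T": "G", "C": "G", "G": "T", "A": "C"}[seq[pos]]
                    break
    raise RuntimeError("could not repair amplicon fixture")  # pragma: no cover


def make_rflp_fixture(flank_bp: int = 60, seed: int = 7) -> tuple[
    str, PrimerPair, str, str
]:
    """Deterministic (template, primers, wt amplicon, mut amplicon) fixture.

    Both amplicons are 357 bp and start/end with the published primer
    sequences.  The wild-type allele carries exactly one Hpy188III site
    (fragments 189 + 168 bp); the mutant allele differs by a two-base
    substitution creating one additional site that splits the 189-bp
    fragment into 122 + 67 bp.  The construction is verified by digestion
    before returning.
    """
    primers = ASSAY_PRIMERS
    fwd = primers.forward
    rev_site = str(_revcomp(primers.reverse))
    rng = np.random.default_rng(seed)
    middle_len = _AMPLICON_LEN - len(fwd) - len(rev_site)
    middle = rng.choice(list("ACGT"), size=middle_len)
    wt = list(fwd) + list(middle) + list(rev_site)

    protected = set(range(len(fwd))) | set(
        range(_AMPLICON_LEN - len(rev_site), _AMPLICON_LEN)
    )
    # plant the constitutive site and the pre-mutation bases
    wt[_WT_SITE : _WT_SITE + 6] = list("TCATGA")
    wt[_MUT_SITE : _MUT_SITE + 6] = list("GAATGA")  # one 2-bp change from a site
    protected |= set(range(_WT_SITE, _WT_SITE + 6))
    protected |= set(range(_MUT_SITE, _MUT_SITE + 6))

    _repair_sites(wt, keep_starts={_WT_SITE}, protected=protected)
    mut = wt.copy()
    mut[_MUT_SITE : _MUT_SITE + 2] = list("TC")
    _repair_sites(mut, keep_starts={_WT_SITE, _MUT_SITE}, protected=protected)
    wt_seq, mut_seq = "".join(wt), "".join(mut)

    assert sorted(digest(wt_seq, HPY188III).fragment_lengths) == [168, 189]
    assert sorted(digest(mut_seq, HPY188III).fragment_lengths) == [67, 122, 168]

    flanks = ["".join(rng.choice(list("ACGT"), size=flank_bp)) for _ in range(2)]
    template = flanks[0] + wt_seq + flanks[1]
    # the flanks must not create extra primer sites
    if template.count(fwd) != 1 or template.count(rev_site) != 1:  # pragma: no cover
        raise RuntimeError("fixture flanks collide with primer sequences")
    return template, primers, wt_seq, mut_seq


def make_nonspecific_template(seed: int = 11, spacer_bp: int = 400) -> str:
    """A template carrying the amplicon twice -> non-specific amplification."""
    _, primers, wt, _ = make_rflp_fixture(seed=seed)
    rng = np.random.default_rng(seed + 1)
    spacer = "".join(rng.choice(list("ACGT"), size=spacer_bp))
    return wt + spacer + wt


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
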