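"""ROH detection against an exhaustive window-enumeration oracle."""

import numpy as np
import pytest

from foundertrace.genmap import PhysicalInterval
from foundertrace.roh import (
    AutozygousSegment,
    Call,
    MarkerGenotypes,
    RohParams,
    detect_roh,
    display_mb,
    intersect_segments,
    segment_length_mb,
)
from foundertrace.simulate import SimulationConfig, simulate_patient

HOM, HET, MIS = Call.HOM_REF, Call.HET, Call.MISSING


def oracle_detect(g: MarkerGenotypes, params: RohParams) -> list[tuple[int, int]]:
    """Enumerate every window with plain loops; return (start_bp, end_bp)."""
    n = g.n_markers
    w = params.window_markers
    if n < w:
        return []
    covered = [False] * n
    for i in range(n - w + 1):
        window = g.calls[i : i + w]
        if (
            int(np.sum(window == Call.HET)) <= params.max_het_per_window
            and int(np.sum(window == Call.MISSING)) <= params.max_missing_per_window
        ):
            for k in range(i, i + w):
                covered[k] = True
    hom = [c in (Call.HOM_REF, Call.HOM_ALT) for c in g.calls]
    out = []
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and covered[j + 1]:
            j += 1
        lo, hi = i, j
        while lo <= hi and not hom[lo]:
            lo += 1
        while hi >= lo and not hom[hi]:
            hi -= 1
        if lo <= hi:
            start, end = int(g.positions[lo]), int(g.positions[hi])
            if end - start + 1 >= params.min_length_bp and hi - lo + 1 >= params.min_markers:
                out.append((start, end))
        i = j + 1
    return out


def _mk(calls, spacing=100_000, sample="s1"):
    calls = np.asarray(calls, dtype=np.int8)
    positions = (np.arange(calls.size) + 1) * spacing
    return MarkerGenotypes("chr9", positions, calls, sample)


class TestDetectRoh:
    def test_all_homozygous_is_one_segment(self):
        g = _mk([HOM] * 1000, spacing=5_000)  # 5 Mb span
        segs = detect_roh(g, RohParams())
        assert len(segs) == 1
        assert segs[0].start_bp == int(g.positions[0])
        assert segs[0].end_bp == int(g.positions[-1])
        assert segs[0].n_markers == 1000 and segs[0].n_het_inside == 0

    def test_alternating_het_yields_nothing(self):
        g = _mk([HOM, HET] * 500)
        params = RohParams(window_markers=2, max_het_per_window=0,
                           min_length_bp=1, min_markers=1)
        assert detect_roh(g, params) == []

    def test_fewer_markers_than_window_warns_not_raises(self, caplog):
        g = _mk([HOM] * 10)
        with caplog.at_level("WARNING"):
            assert detect_roh(g, RohParams(window_markers=25)) == []
        assert "no ROH called" in caplog.text

    def test_terminal_markers_are_homozygous_and_nonoverlapping(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            calls = rng.choice([0, 1, 2, 3], size=2000, p=[0.45, 0.1, 0.4, 0.05])
            g = _mk(calls, spacing=2_000)
            segs = detect_roh(g, RohParams(min_length_bp=10_000, min_markers=10))
            for s in segs:
                i0 = int(np.searchsorted(g.positions, s.start_bp))
                i1 = int(np.searchsorted(g.positions, s.end_bp))
                assert g.calls[i0] in (Call.HOM_REF, Call.HOM_ALT)
                assert g.calls[i1] in (Call.HOM_REF, Call.HOM_ALT)
            for a, b in zip(segs, segs[1:]):
                assert a.end_bp < b.start_bp

    @pytest.mark.parametrize("seed", range(50))
    def test_oracle_equivalence_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 5000))
        # blocks of elevated homozygosity to create realistic candidate runs
        p_hom = rng.uniform(0.55, 0.95)
        calls = rng.choice(
            [0, 1, 2, 3],
            size=n,
            p=[p_hom / 2, 1 - p_hom - 0.02, p_hom / 2, 0.02],
        )
        g = _mk(calls, spacing=int(rng.integers(500, 5_000)))
        params = RohParams(
            window_markers=int(rng.integers(5, 40)),
            max_het_per_window=int(rng.integers(0, 3)),
            max_missing_per_window=int(rng.integers(0, 4)),
            min_length_bp=int(rng.integers(1, 200_000)),
            min_markers=int(rng.integers(1, 60)),
        )
        got = [(s.start_bp, s.end_bp) for s in detect_roh(g, params)]
        assert got == oracle_detect(g, params)

    def test_planted_segment_recovered(self):
        cfg = SimulationConfig(seed=3, true_g=10.0, marker_count=5000)
        g, truth = simulate_patient(cfg)
        segs = detect_roh(g, RohParams())
        # exactly one call overlapping the truth, boundaries within one window
        hits = [s for s in segs if s.start_bp <= truth.end_bp and s.end_bp >= truth.start_bp]
        assert len(hits) == 1
        spacing = cfg.chromosome_length_bp / cfg.marker_count
        slack = RohParams().window_markers * spacing
        assert abs(hits[0].start_bp - truth.start_bp) <= slack
        assert abs(hits[0].end_bp - truth.end_bp) <= slack

    def test_het_dense_flanks_do_not_shift_boundaries(self):
        core = [HOM] * 200
        flank = [HOM, HET] * 50
        spacing = 10_000
        params = RohParams(window_markers=10, max_het_per_window=0,
                           min_length_bp=100_000, min_markers=20)
        bare = detect_roh(_mk(core, spacing), params)
        padded_calls = flank + core + flank
        padded = detect_roh(_mk(padded_calls, spacing), params)
        assert len(bare) == len(padded) == 1
        # same genomic width within one window of markers
        width_bare = bare[0].end_bp - bare[0].start_bp
        width_padded = padded[0].end_bp - padded[0].start_bp
        assert abs(width_bare - width_padded) <= params.window_markers * spacing


class TestIntersectSegments:
    S1 = AutozygousSegment("chr9", 35_096_634, 38_543_655, 100, 0, "p1")
    S2 = AutozygousSegment("chr9", 35_805_740, 40_610_122, 120, 0, "p2")
    GNE = PhysicalInterval("chr9", 36_200_000, 36_260_000)

    def test_published_segments_core(self):
        core = intersect_segments([self.S1, self.S2], self.GNE)
        assert (core.start_bp, core.end_bp) == (35_805_740, 38_543_655)

    def test_single_and_identical(self):
        assert intersect_segments([self.S1], self.GNE).start_bp == self.S1.start_bp
        core = intersect_segments([self.S1, self.S1], self.GNE)
        assert (core.start_bp, core.end_bp) == (self.S1.start_bp, self.S1.end_bp)

    def test_anchor_violation_names_sample(self):
        far = AutozygousSegment("chr9", 1_000, 2_000, 10, 0, "odd_one")
        with pytest.raises(ValueError, match="odd_one"):
            intersect_segments([self.S1, far], self.GNE)

    def test_position_anchor(self):
        core = intersect_segments([self.S1, self.S2], 36_214_000)
        assert (core.start_bp, core.end_bp) == (35_805_740, 38_543_655)


class TestSegmentLength:
    def test_published_lengths(self):
        assert segment_length_mb(self.larger()) == pytest.approx(4.804383)
        assert display_mb(segment_length_mb(self.larger())) == 4.8
        assert segment_length_mb(self.smaller()) == pytest.approx(3.447022)
        assert display_mb(segment_length_mb(self.smaller())) == 3.4

    def test_single_base_segment(self):
        seg = AutozygousSegment("chr9", 100, 100, 1, 0, "s")
        assert segment_length_mb(seg) == pytest.approx(1e-6)

    @staticmethod
    def larger():
        return AutozygousSegment("chr9", 35_805_740, 40_610_122, 1, 0, "wgs")

    @staticmethod
    def smaller():
        return AutozygousSegment("chr9", 35_096_634, 38_543_655, 1, 0, "wes")
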