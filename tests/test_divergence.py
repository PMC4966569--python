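"""Divergence rates, CpG handling, equilibrium GC, selection ratio, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_catalog
from niebtools.core import COMPLEMENT, encode_sequence
from niebtools.divergence import (CHANGE_PAIRS, CLASS_NAMES, BackgroundRates,
                                  ContextSpec, RateProfile, SiteTable,
                                  attach_intraspecies_events, background_rates,
                                  bootstrap_null, build_window_counts,
                                  context_rates, detect_cpg_sites,
                                  detect_isolated_substitutions,
                                  equilibrium_gc, selection_ratio,
                                  tabulate_rates, windowed_pair_selection)

A, C, G, T = 0, 1, 2, 3


def cols(h, c, o, m):
    return {"h": encode_sequence(h), "c": encode_sequence(c),
            "o": encode_sequence(o), "m": encode_sequence(m)}


class TestIsolatedSubstitutions:
    def test_isolated_event_detected(self):
        # flanks identical in all four species; human G->A change at center
        st = detect_isolated_substitutions(cols("TAC", "TGC", "TGC", "TGC"))
        assert st.eligible[1]
        assert st.events[1]
        assert st.anc[1] == G and st.human[1] == A

    def test_identical_column_eligible_no_event(self):
        st = detect_isolated_substitutions(cols("TGC", "TGC", "TGC", "TGC"))
        assert st.eligible[1] and not st.events[1]

    def test_outgroup_disagreement_ineligible(self):
        st = detect_isolated_substitutions(cols("TAC", "TGC", "TAC", "TGC"))
        assert not st.eligible[1]

    def test_gap_in_flank_ineligible(self):
        st = detect_isolated_substitutions(cols("T-CAA", "TGCAA", "TGCAA", "TGCAA"))
        assert not st.eligible[2]
        assert st.eligible[3]

    def test_chimp_plus_one_rule(self):
        c = cols("TAC", "TGC", "TGC", "TCC")
        assert not detect_isolated_substitutions(c).eligible[1]
        st = detect_isolated_substitutions(c, ancestral_rule="chimp_plus_one")
        assert st.eligible[1] and st.events[1]


class TestCpG:
    def test_ng_pattern(self):
        # human TG, others CG: the C position is a CpG site
        flag = detect_cpg_sites(cols("ATGA", "ACGA", "ACGA", "ACGA"))
        assert flag[1] and flag[2]   # strand-symmetric: the G is flagged too

    def test_all_ca_not_cpg(self):
        assert not detect_cpg_sites(cols("ACAA", "ACAA", "ACAA", "ACAA")).any()

    def test_cn_pattern_on_chimp(self):
        flag = detect_cpg_sites(cols("ACGA", "ACAA", "ACGA", "ACGA"))
        assert flag[1]

    def test_strand_symmetric_off(self):
        flag = detect_cpg_sites(cols("ATGA", "ACGA", "ACGA", "ACGA"),
                                strand_symmetric=False)
        assert flag[1] and not flag[2]

    def test_cpg_exclusion_only_touches_strong_rates(self, synthetic_run):
        truth, genome, catalog, sim = synthetic_run
        st = detect_isolated_substitutions(sim.columns["chr1"])
        excl = tabulate_rates({"chr1": st}, catalog, 200, exclude_cpg=True)
        incl = tabulate_rates({"chr1": st}, catalog, 200, exclude_cpg=False)
        # weak-ancestral (A/T) counts identical; strong-ancestral shrink
        assert (excl.eligible[:, [A, T]] == incl.eligible[:, [A, T]]).all()
        assert (excl.inter[:, [A, T], :] == incl.inter[:, [A, T], :]).all()
        assert excl.eligible[:, [C, G]].sum() < incl.eligible[:, [C, G]].sum()


class TestIntraspecies:
    def _sites(self, anc="AAAAAAAAAA"):
        n = len(anc)
        codes = encode_sequence(anc)
        return SiteTable(anc=codes, human=codes.copy(), flank=codes.copy(),
                         eligible=np.ones(n, bool), cpg=np.zeros(n, bool))

    def test_simple_polymorphism(self):
        st = self._sites()
        v = pd.DataFrame({"chrom": ["chr1"], "pos": [4], "ref": ["A"],
                          "alt": ["G"], "af": [0.1]})
        n, _ = attach_intraspecies_events(st, v)
        assert n == 1
        assert st.intra_pos[0] == 4 and st.intra_y[0] == G

    def test_maf_filter(self):
        st = self._sites()
        v = pd.DataFrame({"chrom": ["chr1"], "pos": [4], "ref": ["A"],
                          "alt": ["G"], "af": [0.005]})
        n, _ = attach_intraspecies_events(st, v, maf_min=0.01)
        assert n == 0

    def test_ancestral_is_alt(self):
        # derived REF: ancestral allele sits in ALT, the other direction counts
        st = self._sites("AAAA")
        st.anc[2] = G
        st.flank[2] = G
        v = pd.DataFrame({"chrom": ["chr1"], "pos": [2], "ref": ["A"],
                          "alt": ["G"], "af": [0.6]})
        n, _ = attach_intraspecies_events(st, v)
        assert n == 1 and st.intra_y[0] == A   # G -> A polymorphism

    def test_no_matching_ancestral_excluded(self):
        st = self._sites("AAAA")
        st.anc[2] = T
        st.flank[2] = T
        v = pd.DataFrame({"chrom": ["chr1"], "pos": [2], "ref": ["A"],
                          "alt": ["G"], "af": [0.3]})
        n, excluded = attach_intraspecies_events(st, v)
        assert n == 0 and excluded == 1


class BruteForce:
    """Independent per-site recount of offsets and rates (O(sites * barriers))."""

    @staticmethod
    def offset_side(pos, barriers, max_offset):
        for s, e in barriers:
            if s <= pos < e:
                dl, dr = pos - s + 1, e - pos
                if dl <= dr:
                    return (-dl, "five") if dl <= max_offset else (0, None)
                return (-dr, "three") if dr <= max_offset else (0, None)
        cands = []
        for s, e in barriers:
            if pos >= e:
                cands.append((pos - e + 1, "three"))
            if pos < s:
                cands.append((s - pos, "five"))
        if not cands:
            return 0, None
        dmin = min(d for d, _ in cands)
        if dmin > max_offset:
            return 0, None
        sides = {sd for d, sd in cands if d == dmin}
        return dmin, ("five" if "five" in sides else "three")

    @classmethod
    def rates(cls, st, barriers, max_offset, exclude_cpg=True):
        O = 2 * max_offset + 1
        eligible = np.zeros((O, 4), dtype=int)
        inter = np.zeros((O, 4, 4), dtype=int)
        intra = np.zeros((O, 4, 4), dtype=int)
        intra_map = {}
        for p, y in zip(st.intra_pos, st.intra_y):
            intra_map.setdefault(int(p), []).append(int(y))
        for i in range(len(st)):
            if not st.eligible[i] or (exclude_cpg and st.cpg[i]):
                continue
            off, side = cls.offset_side(i, barriers, max_offset)
            if off == 0:
                continue
            x, hy = int(st.anc[i]), int(st.human[i])
            if side == "five":
                x, hy = int(COMPLEMENT[x]), int(COMPLEMENT[hy])
            eligible[off + max_offset, x] += 1
            if hy != x:
                inter[off + max_offset, x, hy] += 1
            for y in intra_map.get(i, []):
                yy = int(COMPLEMENT[y]) if side == "five" else y
                intra[off + max_offset, x, yy] += 1
        return eligible, inter, intra


class TestTabulateRates:
    def test_rate_arithmetic(self):
        # 2 events among 100 eligible ancestral-G sites at one offset
        O = 21
        eligible = np.zeros((O, 4), int)
        inter = np.zeros((O, 4, 4), int)
        eligible[15, G] = 100
        inter[15, G, A] = 2
        rp = RateProfile(np.arange(-10, 11), eligible, inter, np.zeros_like(inter))
        assert rp.d_inter()[15, G, A] == pytest.approx(0.02)

    def test_no_events_zero_rates_defined(self):
        O = 5
        eligible = np.ones((O, 4), int)
        z = np.zeros((O, 4, 4), int)
        rp = RateProfile(np.arange(-2, 3), eligible, z, z)
        assert np.nansum(rp.d_inter()) == 0.0
        assert not np.isnan(rp.d_inter()[0, 0, 1])

    def test_streamed_equals_brute_force_on_toy_table(self, rng):
        # 10-kb toy alignment with barriers; independent O(L*B) recount
        from niebtools.simulate import SyntheticTruth, generate_genomes, simulate_divergence
        truth = SyntheticTruth(barrier_rate=1 / 600.0)
        genome, catalog = generate_genomes(truth, {"chr1": 10_000}, seed=11)
        sim = simulate_divergence(truth, genome, catalog, np.random.default_rng(12))
        st = detect_isolated_substitutions(sim.columns["chr1"])
        attach_intraspecies_events(st, sim.variants, maf_min=0.0)
        rp = tabulate_rates({"chr1": st}, catalog, 120)
        starts, ends = catalog.intervals.per_chrom("chr1")
        be, bi, bt = BruteForce.rates(st, list(zip(starts, ends)), 120)
        assert (rp.eligible == be).all()
        assert (rp.inter == bi).all()
        assert (rp.intra == bt).all()


class TestEquilibriumGC:
    def test_uniform_rates(self):
        m = np.full((4, 4), 0.001)
        assert equilibrium_gc(m) == pytest.approx(0.5)

    def test_two_to_one_ws_ratio(self):
        m = np.full((4, 4), 0.001)
        for x in (A, T):
            for y in (C, G):
                m[x, y] = 0.002
        assert equilibrium_gc(m) == pytest.approx(2.0 / 3.0)

    def test_absorbing_strong_class(self):
        m = np.zeros((4, 4))
        for x in (A, T):
            for y in (C, G):
                m[x, y] = 0.002
        m[C, G] = m[G, C] = 0.001
        assert equilibrium_gc(m) == pytest.approx(1.0)

    def test_complement_relabel_invariance(self, rng):
        m = rng.random((4, 4)) * 0.01
        np.fill_diagonal(m, 0)
        sym = (m + m[np.ix_(COMPLEMENT[:4], COMPLEMENT[:4])]) / 2
        relabeled = sym[np.ix_(COMPLEMENT[:4], COMPLEMENT[:4])]
        assert equilibrium_gc(sym) == pytest.approx(equilibrium_gc(relabeled))

    def test_degenerate_matrix_undefined(self):
        assert np.isnan(equilibrium_gc(np.zeros((4, 4))))


class TestBackgroundAndSelection:
    def test_background_matches_global_rate_in_homogeneous_data(self, synthetic_run):
        truth, genome, catalog, sim = synthetic_run
        st = detect_isolated_substitutions(sim.columns["chr1"])
        from niebtools.catalog import internieb_regions
        regions = internieb_regions(catalog)
        bg = background_rates({"chr1": st}, regions)
        # transition rate recovered within sampling error
        assert bg.rate_inter()[A, G] == pytest.approx(truth.transition_rate, rel=0.25)
        assert bg.rate_inter()[A, C] == pytest.approx(truth.transversion_rate, rel=0.4)

    def test_no_large_regions_errors(self):
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500],
                                "d": [500]})
        with pytest.raises(ValueError, match="wider than"):
            background_rates({}, regions)

    def test_clipped_central_span(self):
        # a 900-bp region contributes exactly its central 600 bp
        st = SiteTable(anc=np.full(1000, A, np.uint8),
                       human=np.full(1000, A, np.uint8),
                       flank=np.full(1000, A, np.uint8),
                       eligible=np.ones(1000, bool), cpg=np.zeros(1000, bool))
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [950],
                                "d": [900]})
        bg = background_rates({"chr1": st}, regions)
        assert bg.eligible[A] == 600

    def test_selection_ratio_arithmetic(self):
        eligible = np.full((1, 4), 1000)
        inter = np.zeros((1, 4, 4), int)
        intra = np.zeros((1, 4, 4), int)
        inter[0, C, A] = 20     # dInter = 0.02
        intra[0, C, A] = 4      # dIntra = 0.004
        rp = RateProfile(np.array([5]), eligible, inter, intra)
        bg = BackgroundRates(np.full(4, 1000),
                             np.full((4, 4), 10),    # bgInter = 0.01
                             np.full((4, 4), 4))     # bgIntra = 0.004
        s = selection_ratio(rp, bg)
        assert s[0, C, A] == pytest.approx(2.0)

    def test_neutral_identity(self):
        eligible = np.full((3, 4), 500)
        inter = np.full((3, 4, 4), 5)
        intra = np.full((3, 4, 4), 5)
        rp = RateProfile(np.array([1, 2, 3]), eligible, inter, intra)
        bg = BackgroundRates(np.full(4, 500), np.full((4, 4), 5), np.full((4, 4), 5))
        s = selection_ratio(rp, bg)
        assert np.allclose(s[np.isfinite(s)], 1.0)

    def test_zero_intra_rate_undefined_not_infinite(self):
        eligible = np.full((1, 4), 100)
        inter = np.full((1, 4, 4), 5)
        intra = np.zeros((1, 4, 4), int)
        rp = RateProfile(np.array([1]), eligible, inter, intra)
        bg = BackgroundRates(np.full(4, 100), np.full((4, 4), 5), np.full((4, 4), 5))
        s = selection_ratio(rp, bg)
        assert np.isnan(s[0, C, A])


class TestBootstrap:
    def test_degenerate_constant_counts(self):
        from niebtools.divergence import WindowCounts
        inter = np.full((40, 10, 6), 3, np.int32)
        intra = np.full((40, 10, 6), 3, np.int32)
        elig = np.full((40, 10, 2), 100, np.int32)
        bg = BackgroundRates(np.full(4, 100), np.full((4, 4), 3), np.full((4, 4), 3))
        # background pair rates equal window pair rates -> every rep S = 1
        null = bootstrap_null(WindowCounts(inter, intra, elig), bg, reps=200,
                              rng=np.random.default_rng(0))
        assert np.allclose(null.ci_low, 1.0)
        assert np.allclose(null.ci_high, 1.0)

    def test_few_reps_warns(self):
        from niebtools.divergence import WindowCounts
        wc = WindowCounts(np.ones((5, 4, 6), np.int32),
                          np.ones((5, 4, 6), np.int32),
                          np.full((5, 4, 2), 10, np.int32))
        bg = BackgroundRates(np.full(4, 10), np.ones((4, 4)), np.ones((4, 4)))
        with pytest.warns(UserWarning):
            bootstrap_null(wc, bg, reps=50, rng=np.random.default_rng(0))


class TestContextRates:
    @staticmethod
    def _flank_sites(triplet, human_mid):
        """200 all-A sites with ``triplet`` planted right of a barrier end."""
        anc = np.zeros(200, dtype=np.uint8)
        anc[119:122] = encode_sequence(triplet)
        human = anc.copy()
        human[120] = encode_sequence(human_mid)[0]
        eligible = np.zeros(200, bool)
        eligible[119:122] = True
        return SiteTable(anc=anc, human=human, flank=anc.copy(),
                         eligible=eligible, cpg=np.zeros(200, bool))

    def test_ttt_to_tat_event(self):
        st = self._flank_sites("TTT", "A")
        cat = make_catalog([("chr1", 50, 86)])   # sites 119..121 are 3' flank
        prof = context_rates({"chr1": st}, cat, ["tTt>tAt"], 100)["tTt>tAt"]
        assert prof.eligible.sum() == 1
        assert prof.inter.sum() == 1

    def test_sts_matches_c_and_g_flanks(self):
        st = self._flank_sites("CTG", "T")      # no event, just eligibility
        cat = make_catalog([("chr1", 50, 86)])
        prof = context_rates({"chr1": st}, cat, ["sTs>sAs"], 100)["sTs>sAs"]
        assert prof.eligible.sum() == 1   # cTg qualifies (s matches c and g)

    def test_streamed_equals_brute_force(self):
        from niebtools.simulate import SyntheticTruth, generate_genomes, simulate_divergence
        truth = SyntheticTruth(barrier_rate=1 / 600.0)
        genome, catalog = generate_genomes(truth, {"chr1": 10_000}, seed=13)
        sim = simulate_divergence(truth, genome, catalog, np.random.default_rng(14))
        st = detect_isolated_substitutions(sim.columns["chr1"])
        spec = ContextSpec.parse("tTt>tAt")
        rc = spec.revcomp()
        prof = context_rates({"chr1": st}, catalog, [spec], 120)["tTt>tAt"]
        starts, ends = catalog.intervals.per_chrom("chr1")
        barriers = list(zip(starts, ends))
        O = 241
        elig = np.zeros(O, int)
        ev = np.zeros(O, int)
        for i in range(1, len(st) - 1):
            if not st.eligible[i] or st.cpg[i]:
                continue
            off, side = BruteForce.offset_side(i, barriers, 120)
            if off == 0:
                continue
            use = rc if side == "five" else spec
            if (int(st.anc[i]) == use.x and int(st.flank[i - 1]) in use.left
                    and int(st.flank[i + 1]) in use.right):
                elig[off + 120] += 1
                if int(st.human[i]) == use.y:
                    ev[off + 120] += 1
        assert (prof.eligible == elig).all()
        assert (prof.inter == ev).all()


class TestWindowedSelection:
    def test_window_pooling_and_classes(self, synthetic_run):
        truth, genome, catalog, sim = synthetic_run
        st = detect_isolated_substitutions(sim.columns["chr1"])
        attach_intraspecies_events(st, sim.variants)
        from niebtools.catalog import internieb_regions
        regions = internieb_regions(catalog)
        bg = background_rates({"chr1": st}, regions)
        rp = tabulate_rates({"chr1": st}, catalog, 200)
        win = windowed_pair_selection(rp, bg, window=10)
        assert set(win["pair"]) == set(CLASS_NAMES)
        # pooled SW counts equal the sum of the member pairs
        at_zero = win[win["offset"] == win["offset"].min()]
        sw = at_zero[at_zero["pair"] == "SW"]["inter"].iloc[0]
        ga = at_zero[at_zero["pair"] == "GA/CT"]["inter"].iloc[0]
        ca = at_zero[at_zero["pair"] == "CA/GT"]["inter"].iloc[0]
        assert sw == ga + ca
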