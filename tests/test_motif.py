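import math
from fractions import Fraction

import numpy as np
import pytest

from phosflow.motif import (
    CAMKII_MOTIF,
    CDK_MOTIF,
    MotifPattern,
    NmerSet,
    build_foreground,
    count_motif_matches,
    count_peptide_motif_matches,
    extract_nmers,
    plogo_loe,
)
from phosflow.differential import SiteStat
from phosflow.simulate import SimConfig, simulate_motif_sites

from conftest import make_psm


def exact_loe(k, K, n, N):
    """Exhaustive-enumeration hypergeometric log-odds oracle (exact
    rational tail sums; signed by enrichment direction)."""
    denom = math.comb(N, n)
    lo = max(0, n + K - N)
    hi = min(n, K)
    upper = sum(math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(k, hi + 1))
    lower = sum(math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(lo, k + 1))
    if n == 0 or upper == 0 or lower == 0:
        return 0.0
    raw = -(math.log10(upper) - math.log10(lower))
    direction = (k * N > K * n) - (k * N < K * n)
    return direction * abs(raw)


class TestExtractNmers:
    def test_padded_window_positional_bookkeeping(self):
        psm = make_psm(sequence="SVYTEIK", sites=(("Y", 3, 0.99),))
        nmers, report = extract_nmers([psm])
        assert nmers.nmers == ["AAAAASVyTEIKAAA"]
        assert nmers.nmers[0][7] == "y"
        assert report.n_rejected == 0

    def test_two_localized_sites_give_two_windows(self):
        psm = make_psm(sequence="SVYTEIK",
                       sites=(("Y", 3, 0.99), ("T", 4, 0.9)))
        nmers, _ = extract_nmers([psm])
        assert len(nmers) == 2

    def test_ambiguous_site_excluded(self):
        psm = make_psm(sites=(("Y", 3, 0.6),))
        nmers, report = extract_nmers([psm])
        assert len(nmers) == 0
        assert report.n_below_localization == 1

    def test_localization_threshold_is_strict(self):
        psm = make_psm(sites=(("Y", 3, 0.75),))
        nmers, _ = extract_nmers([psm])
        assert len(nmers) == 0

    def test_protein_context_extends_flanks(self):
        protein = "MMMMMMMMMMSVYTEIKWWWWWWW"
        psm = make_psm(sequence="SVYTEIK", sites=(("Y", 3, 0.99),))
        nmers, _ = extract_nmers([psm], {"P12345": protein})
        assert nmers.nmers == ["MMMMMSVyTEIKWWW"]

    def test_identical_windows_median_combined(self):
        psms = [make_psm(scan_id=f"s{i}") for i in range(3)]
        nmers, _ = extract_nmers([*psms], values=[2.0, 4.0, 8.0])
        combined = nmers.combine_identical()
        assert len(combined) == 1
        assert combined.values == [4.0]
        assert combined.weights_combined


class TestPlogoLoe:
    def test_forced_composition_gives_zero(self):
        # K = N: the residue occupies that position in every background
        fg = ["AAAAAAAsRAAAAAA"] * 3
        bg = ["AAAAAAAsRAAAAAA"] * 3 + ["AAAAAAAsRCCCCCC"] * 7
        logo = plogo_loe(fg, bg)
        assert logo.loe.loc[1, "R"] == 0.0

    def test_foreground_equal_background_all_zero(self, rng):
        _, bg, _ = simulate_motif_sites(SimConfig(seed=3,
                                                  motif_n_foreground=0,
                                                  motif_n_background=40))
        logo = plogo_loe(bg, bg)
        assert (logo.loe.values == 0).all()

    def test_fixture_matches_enumeration_oracle(self):
        # N=10, K=4 at +1 'R'; n=5, k=4
        bg = (["AAAAAAAsRAAAAAA"] * 4 + ["AAAAAAAsCAAAAAA"] * 6)
        fg = ["AAAAAAAsRAAAAAA"] * 4 + ["AAAAAAAsCAAAAAA"]
        logo = plogo_loe(fg, bg)
        assert logo.loe.loc[1, "R"] == pytest.approx(
            exact_loe(4, 4, 5, 10), abs=1e-9)

    def test_agreement_with_oracle_on_random_small_fixtures(self, rng):
        alphabet = np.array(list("ARND"))
        for _ in range(20):
            N = int(rng.integers(4, 25))
            n = int(rng.integers(1, N + 1))
            bg = ["".join(a) for a in alphabet[
                rng.integers(0, 4, (N, 15))]]
            bg = [b[:7] + "s" + b[8:] for b in bg]
            idx = rng.choice(N, n, replace=False)
            fg = [bg[i] for i in idx]
            logo = plogo_loe(fg, bg)
            for pos in (-7, -1, 3):
                for aa in "ARND":
                    k = sum(x[7 + pos] == aa for x in fg)
                    K = sum(x[7 + pos] == aa for x in bg)
                    assert logo.loe.loc[pos, aa] == pytest.approx(
                        exact_loe(k, K, n, N), abs=1e-9)

    def test_order_invariance(self, rng):
        _, bg, _ = simulate_motif_sites(SimConfig(seed=4,
                                                  motif_n_foreground=30,
                                                  motif_n_background=100))
        fg = bg[:30]
        logo1 = plogo_loe(fg, bg)
        perm = list(rng.permutation(len(bg)))
        logo2 = plogo_loe(fg[::-1], [bg[i] for i in perm])
        np.testing.assert_allclose(logo1.loe.values, logo2.loe.values,
                                   atol=1e-12)

    def test_planted_enrichment_attains_maximum(self):
        fg, bg, ledger = simulate_motif_sites(SimConfig(seed=11))
        logo = plogo_loe(fg, bg)
        pos, res = logo.max_cell()
        assert (pos, res) == (ledger["plant"]["position"],
                              ledger["plant"]["residue"])

    def test_empty_foreground_warns(self):
        with pytest.warns(RuntimeWarning, match="empty"):
            logo = plogo_loe([], ["AAAAAAAsAAAAAAA"])
        assert (logo.loe.values == 0).all()


class TestBuildForeground:
    @pytest.mark.parametrize("fc,p,expected", [
        (1.3, 0.03, True),
        (0.7, 0.049, True),
        (1.3, 0.2, False),
        (1.0, 1e-5, False),
        (1.25, 0.03, False),  # strict FC bound
    ])
    def test_selection_rule(self, fc, p, expected):
        stat = SiteStat("key", fc, p, 4, 4)
        assert (("key" in build_foreground([stat])) is expected)


class TestMotifPatterns:
    def test_camkii_worked_example_counts_four(self):
        # F@-4, R@-3, Q@-2, wildcard@-1, center s, V@+1 -> F,R,Q,V counted
        nmer = "AAAFRQWsVAAAAAA"
        assert nmer[7] == "s"
        assert count_motif_matches(nmer, CAMKII_MOTIF) == 4

    def test_cdk_worked_example_counts_three(self):
        nmer = "AAAAAAAsPKKAAAA"
        assert count_motif_matches(nmer, CDK_MOTIF) == 3

    def test_no_matching_residues(self):
        nmer = "GGGGGGGsGGGGGGG"
        assert count_motif_matches(nmer, CAMKII_MOTIF) == 0

    def test_count_bounded_by_counted_positions(self, rng):
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for pattern in (CAMKII_MOTIF, CDK_MOTIF):
            bound = len(pattern.counted_positions)
            for _ in range(500):
                chars = alphabet[rng.integers(0, 20, 15)]
                nmer = "".join(chars[:7]) + "s" + "".join(chars[8:])
                assert 0 <= count_motif_matches(nmer, pattern) <= bound

    def test_multisite_peptide_takes_max(self):
        low = "GGGGGGGsGGGGGGG"
        high = "AAAAAAAsPKKAAAA"
        assert count_peptide_motif_matches([low, high], CDK_MOTIF) == 3

    def test_pattern_parser_roundtrip(self):
        p = MotifPattern.from_string("X", "[st]-P-K-K")
        assert p.counted_positions == (1, 2, 3)
        assert p.classes[p.center_index] == frozenset("st")
        with pytest.raises(ValueError, match="phospho-center"):
            MotifPattern.from_string("bad", "P-K-K")


class TestNmerSetInvariants:
    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            NmerSet(["AAAsAAA"])

    def test_center_must_be_phospho(self):
        with pytest.raises(ValueError):
            NmerSet(["AAAAAAAQAAAAAAA"])
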