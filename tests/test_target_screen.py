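import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirdep import (
    GeneSet,
    MatureMiRNA,
    build_target_report,
    candidate_targets,
    correlate_with_mir,
    reinduction_filter,
    scan_seed_sites,
)
from mirdep.datasets import target_screen_table
from mirdep.target_screen import count_significant_inverse

from conftest import toy_matrix
from test_dependency import fake_contrast


def brute_force_sites(utr: str, mir: MatureMiRNA):
    """Independent scanner: explicit substring comparison against Biopython
    reverse complements, most specific type per seed-match locus."""
    utr = utr.upper().replace("T", "U")
    core6 = str(Seq(mir.sequence[1:7]).reverse_complement_rna())
    core7 = str(Seq(mir.sequence[1:8]).reverse_complement_rna())
    found = []
    for i in range(len(utr) - 5):
        if utr[i : i + 6] != core6:
            continue
        m8 = i >= 1 and utr[i - 1 : i + 6] == core7
        a1 = utr[i + 6 : i + 7] == "A"
        if m8 and a1:
            found.append((i - 1, i + 7, "8mer"))
        elif m8:
            found.append((i - 1, i + 6, "7mer-m8"))
        elif a1:
            found.append((i, i + 7, "7mer-A1"))
        else:
            found.append((i, i + 6, "6mer"))
    return found


class TestMatureMiRNA:
    def test_seed_is_positions_2_to_8(self, mir):
        assert mir.seed == "UAAUGCU"
        assert len(mir.sequence) == 23

    def test_dna_input_normalised(self):
        m = MatureMiRNA(name="x", sequence="ttaatgctaattgtgataggggt")
        assert m.seed == "UAAUGCU"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match=">=8"):
            MatureMiRNA(name="x", sequence="UAAUGC")


class TestScanSeedSites:
    def test_known_8mer_site(self, mir):
        sites = scan_seed_sites("GGAGCAUUAAGG", mir)
        assert len(sites) == 1
        site = sites[0]
        assert (site.start, site.end, site.site_type, site.match) == (2, 10, "8mer", "AGCAUUAA")

    def test_case_and_alphabet_invariance(self, mir):
        assert scan_seed_sites("ggagcattaagg", mir) == scan_seed_sites("GGAGCAUUAAGG", mir)

    def test_no_match(self, mir):
        assert scan_seed_sites("CCCCCCCC", mir) == []

    def test_invalid_character_position_reported(self, mir):
        with pytest.raises(ValueError, match="position 4"):
            scan_seed_sites("GGAGXCAUUAA", mir)

    @pytest.mark.parametrize(
        "utr, expected_type",
        [
            ("CCAGCAUUAACC", "8mer"),      # m8 pairing + A1
            ("CCAGCAUUACC", "7mer-m8"),    # m8 pairing, no A
            ("CCGCAUUAACC", "7mer-A1"),    # no m8, A1 adenine present
            ("CCGCAUUACC", "6mer"),        # bare core match
        ],
    )
    def test_site_type_classification(self, mir, utr, expected_type):
        sites = scan_seed_sites(utr, mir)
        assert [s.site_type for s in sites] == [expected_type]

    def test_agrees_with_brute_force_on_random_utrs(self, mir):
        rng = np.random.default_rng(99)
        for _ in range(200):
            utr = "".join(rng.choice(list("ACGU"), size=rng.integers(10, 300)))
            ours = [(s.start, s.end, s.site_type) for s in scan_seed_sites(utr, mir)]
            assert ours == brute_force_sites(utr, mir)

    def test_specificity_hierarchy_counts(self, mir):
        """Relaxing specificity strictly increases matches: every reported
        locus contains a 6mer core, so 6mer-only counting >= typed counting."""
        rng = np.random.default_rng(17)
        utr = "".join(rng.choice(list("ACGU"), size=2000))
        sites = scan_seed_sites(utr, mir)
        core6 = str(Seq(mir.sequence[1:7]).reverse_complement_rna())
        n_core = sum(1 for i in range(len(utr)) if utr[i : i + 6] == core6)
        assert len(sites) == n_core
        for s in sites:
            assert core6 in s.match


class TestScreenFilters:
    def test_repression_filter(self):
        fc_wt = fake_contrast({"Mafb": 0.37, "Kept": 0.5, "Out": 1.5})
        universe = GeneSet(name="u", members=["Mafb", "Kept", "Out"])
        kept = candidate_targets(fc_wt, universe)
        assert kept.members == ["Mafb", "Kept"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            candidate_targets(fake_contrast({"g": 1.0}), GeneSet(name="u", members=[]))

    def test_reinduction_thresholds(self):
        cross = fake_contrast({"Bat5": 2.07, "weak": 1.01, "down": 0.9})
        cands = GeneSet(name="c", members=["Bat5", "weak", "down"])
        reinduced, top, frac = reinduction_filter(cands, cross)
        assert "Bat5" in reinduced and "Bat5" in top
        assert "weak" in reinduced and "weak" not in top
        assert "down" not in reinduced and "down" not in top
        assert frac == pytest.approx(2 / 3)

    def test_planted_targets_survive_screen(self, small_study, small_contrasts):
        _, _, truth = small_study
        universe = GeneSet(name="u", members=truth.target_probes)
        cands = candidate_targets(small_contrasts["wt"], universe)
        assert len(cands) >= len(universe) - 1
        reinduced, top, frac = reinduction_filter(cands, small_contrasts["cross_ko"])
        assert frac > 0.9

    def test_screen_invariant_to_gene_order(self, small_study, small_contrasts):
        _, _, truth = small_study
        members = truth.target_probes
        fwd = candidate_targets(small_contrasts["wt"], GeneSet(name="u", members=members))
        rev = candidate_targets(small_contrasts["wt"], GeneSet(name="u", members=members[::-1]))
        assert set(fwd.members) == set(rev.members)


class TestCorrelateWithMir:
    def test_perfect_anticorrelation(self):
        mir_vec = np.array([1.0, 2.0, 3.0, 4.0])
        m = toy_matrix((10.0 - mir_vec)[None, :])
        out = correlate_with_mir(m, mir_vec, ["p0"])
        assert out.loc["p0", "r"] == pytest.approx(-1.0)

    def test_hand_vectors_match_textbook_formula(self):
        x = np.array([1.0, 2.0, 2.5, 4.0, 5.5, 6.0])
        y = np.array([3.0, 1.0, 4.0, 2.0, 0.5, 1.5])
        m = toy_matrix(y[None, :])
        out = correlate_with_mir(m, x, ["p0"])
        # brute-force sums
        n = 6
        r = (n * (x * y).sum() - x.sum() * y.sum()) / np.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(abs(t), df=n - 2)
        assert out.loc["p0", "r"] == pytest.approx(r, abs=1e-12)
        assert out.loc["p0", "p"] == pytest.approx(p, abs=1e-12)

    def test_null_exceeds_critical_value_at_expected_rate(self):
        """Independent gene vectors at n=11: ~5% beyond the p=0.05 critical R."""
        rng = np.random.default_rng(2)
        genes = rng.normal(size=(1000, 11))
        mir_vec = rng.normal(size=11)
        out = correlate_with_mir(toy_matrix(genes), mir_vec, [f"p{i}" for i in range(1000)])
        t_crit = stats.t.ppf(0.975, df=9)
        r_crit = t_crit / np.sqrt(9 + t_crit**2)
        frac = float((out["r"].abs() > r_crit).mean())
        assert 0.03 <= frac <= 0.07
        assert frac == pytest.approx((out["p"] < 0.05).mean(), abs=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0.01, max_value=50), st.floats(min_value=-10, max_value=10),
    )
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(4)
        mir_vec = rng.normal(size=8)
        gene = rng.normal(size=(1, 8))
        base = correlate_with_mir(toy_matrix(gene), mir_vec, ["p0"])
        scaled = correlate_with_mir(toy_matrix(gene * scale + shift), mir_vec, ["p0"])
        assert scaled.loc["p0", "r"] == pytest.approx(base.loc["p0", "r"], abs=1e-9)

    def test_zero_variance_gene_flagged(self):
        m = toy_matrix(np.ones((1, 5)))
        out = correlate_with_mir(m, np.arange(5.0), ["p0"])
        assert bool(out.loc["p0", "degenerate"])
        assert np.isnan(out.loc["p0", "r"])


class TestTargetReport:
    def test_published_rows_reingested_count_sixteen_significant(self):
        table = target_screen_table()
        assert len(table) == 18
        assert count_significant_inverse(table["r"], table["r_p"]) == 16

    def test_report_sorted_ascending_r_with_negative_correlations(
        self, small_study, small_contrasts
    ):
        matrix, _, truth = small_study
        top = GeneSet(name="top", members=truth.target_probes)
        correlations = correlate_with_mir(matrix, truth.mir_vector, top)
        report = build_target_report(
            top, correlations, small_contrasts["wt"], small_contrasts["cross_ko"],
            small_contrasts["ko"], symbols=matrix.gene_symbols,
        )
        assert (report["r"] < 0).all()
        assert (report["r"] < -0.5).all()  # planted inverse coupling is strong
        assert list(report["r"]) == sorted(report["r"])
        assert report.attrs["n_significant"] == len(report)

    def test_empty_top_set_gives_empty_report(self, small_contrasts):
        report = build_target_report(
            GeneSet(name="top", members=[]), pd.DataFrame(columns=["r", "p"]),
            small_contrasts["wt"], small_contrasts["cross_ko"], small_contrasts["ko"],
        )
        assert report.empty
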