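"""Codon-usage statistics: RSCU, dRSCU, class enrichment, length bias."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wobblelab import codon
from wobblelab.codon import (CODON_TO_AA, FAMILIES, SENSE_CODONS,
                             STOP_CODONS, CodonClassSpec, CodonError,
                             compare_codon_usage, codon_class_enrichment,
                             length_bias_test, mann_whitney, rscu_profile)


def brute_force_rscu(seq: str) -> dict[str, float]:
    """Independent oracle: plain codon counting + the RSCU definition."""
    counts: dict[str, int] = {}
    for i in range(0, len(seq), 3):
        c = seq[i:i + 3]
        if c not in STOP_CODONS:
            counts[c] = counts.get(c, 0) + 1
    out = {}
    for aa, fam in FAMILIES.items():
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            continue
        for c in fam:
            out[c] = counts.get(c, 0) * len(fam) / total
    return out


def random_cds(rng, n_codons=None) -> str:
    n = n_codons or int(rng.integers(10, 200))
    body = rng.choice(len(SENSE_CODONS), size=n)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


def brute_force_mwu_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(ix):
        xs = [pooled[i] for i in ix]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(ix)]
        u = 0.0
        for a in xs:
            for b in ys:
                u += (a > b) + 0.5 * (a == b)
        return u

    u_obs = u_stat(tuple(range(n1)))
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    n = len(us)
    lo = sum(u <= u_obs for u in us) / n
    hi = sum(u >= u_obs for u in us) / n
    return min(1.0, 2 * min(lo, hi))


class TestRSCUProfile:
    def test_hand_example_lysine_bias(self):
        # Lys counts 2 (AAA) and 1 (AAG): RSCU 2/1.5 and 1/1.5
        prof = rscu_profile("ATGAAAAAGAAATGG", "g")
        assert prof["AAA"] == pytest.approx(4 / 3)
        assert prof["AAG"] == pytest.approx(2 / 3)
        assert prof["ATG"] == 1.0
        assert prof["TGG"] == 1.0

    def test_uniform_usage_gives_all_ones(self):
        seq = "".join(SENSE_CODONS)
        prof = rscu_profile(seq, "g")
        assert set(prof.rscu) == set(SENSE_CODONS)
        assert all(v == pytest.approx(1.0) for v in prof.rscu.values())

    def test_matches_brute_force_oracle_on_random_cds(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            seq = random_cds(rng)
            prof = rscu_profile(seq, "g")
            oracle = brute_force_rscu(seq)
            assert set(prof.rscu) == set(oracle)
            for c, v in oracle.items():
                assert prof.rscu[c] == pytest.approx(v, abs=1e-12)

    def test_family_sums_equal_family_size(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            prof = rscu_profile(random_cds(rng), "g")
            for aa, fam_counts in prof.family_counts.items():
                total = sum(prof.rscu[c] for c in fam_counts)
                assert total == pytest.approx(len(FAMILIES[aa]), abs=1e-9)

    def test_absent_families_are_omitted_not_zero(self):
        prof = rscu_profile("ATGAAATAA", "g")
        assert "GGC" not in prof.rscu  # Gly never observed
        assert prof["AAG"] == 0.0      # Lys family observed, AAG unused

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(CodonError, match="multiple of 3"):
            rscu_profile("ATGAA", "g")

    def test_ambiguous_bases_rejected(self):
        with pytest.raises(CodonError, match="ACGT"):
            rscu_profile("ATGNNNTAA", "g")

    def test_internal_stop_warns_but_computes(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            prof = rscu_profile("ATGTAAAAATAA", "g")
        assert "internal stop" in caplog.text
        assert prof["AAA"] == pytest.approx(2.0)

    def test_matches_seqinr_uco_reference(self, tmp_path):
        """Cross-check against the seqinr::uco RSCU implementation in R."""
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(7)
        seqs = [random_cds(rng, 80) for _ in range(3)]
        script = tmp_path / "uco.R"
        script.write_text(
            "suppressMessages(library(seqinr))\n"
            "seqs <- commandArgs(trailingOnly=TRUE)\n"
            "for (s in seqs) {\n"
            "  r <- uco(s2c(tolower(s)), index='rscu')\n"
            "  cat(paste(toupper(names(r)), r, sep='=', collapse=' '), '\\n')\n"
            "}\n")
        res = subprocess.run(["Rscript", str(script)] + seqs,
                             capture_output=True, text=True, check=True)
        for line, seq in zip(res.stdout.strip().splitlines(), seqs):
            ref = dict(kv.split("=") for kv in line.split())
            prof = rscu_profile(seq, "g")
            for c, v in prof.rscu.items():
                assert float(ref[c]) == pytest.approx(v, abs=1e-8)


class TestCompareCodonUsage:
    def _profiles(self, rscu_values, codon_name="AAA"):
        out = []
        for i, v in enumerate(rscu_values):
            fam = FAMILIES[CODON_TO_AA[codon_name]]
            vec = {c: (v if c == codon_name else
                       (len(fam) - v) / (len(fam) - 1)) for c in fam}
            out.append(codon.RSCUVector(f"g{i}", vec,
                                        {CODON_TO_AA[codon_name]:
                                         {c: 1 for c in fam}}))
        return out

    def test_identical_sets_give_zero_delta(self):
        rng = np.random.default_rng(2)
        profs = [rscu_profile(random_cds(rng), f"g{i}") for i in range(5)]
        res = compare_codon_usage(profs, profs)
        assert (res.per_codon["delta_rscu"] == 0).all()

    def test_separated_samples_exact_p(self):
        up = self._profiles([0.5, 0.6, 0.7])
        down = self._profiles([1.3, 1.4, 1.5])
        res = compare_codon_usage(up, down)
        row = res.per_codon.loc["AAA"]
        assert row["delta_rscu"] == pytest.approx(-0.8)
        assert row["u"] == 0.0
        assert row["p"] == pytest.approx(0.1)

    def test_antisymmetric_under_set_swap(self):
        rng = np.random.default_rng(3)
        a = [rscu_profile(random_cds(rng), f"a{i}") for i in range(6)]
        b = [rscu_profile(random_cds(rng), f"b{i}") for i in range(6)]
        fwd = compare_codon_usage(a, b).per_codon
        rev = compare_codon_usage(b, a).per_codon
        assert (fwd["delta_rscu"] + rev["delta_rscu"] == 0).all()

    def test_empty_side_raises_naming_it(self):
        rng = np.random.default_rng(4)
        profs = [rscu_profile(random_cds(rng), "g")]
        with pytest.raises(ValueError, match="down set is empty"):
            compare_codon_usage(profs, [])

    def test_sparse_codons_skipped(self):
        up = self._profiles([0.5, 0.6])
        down = self._profiles([1.3, 1.4, 1.5])
        res = compare_codon_usage(up, down, min_genes=3)
        assert "AAA" in res.skipped


class TestMannWhitney:
    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(20):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_complete_ties_give_p_one(self):
        _, p = mann_whitney(np.ones(4), np.ones(5))
        assert p == 1.0

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(5)
        x = np.round(rng.normal(size=40), 1)
        y = np.round(rng.normal(0.8, size=40), 1)
        _, p = mann_whitney(x, y)
        from scipy import stats
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic").pvalue
        assert p == pytest.approx(ref)


class TestCodonClassEnrichment:
    def test_default_class_spec(self):
        spec = CodonClassSpec()
        assert spec.class_a == {"AAA", "CAA", "GAA"}
        assert spec.class_b == {"AAG", "CAG", "GAG"}
        assert not (spec.class_a | spec.class_b) & STOP_CODONS

    def test_overlapping_classes_rejected(self):
        with pytest.raises(CodonError, match="disjoint"):
            CodonClassSpec(class_a={"AAA"}, class_b={"AAA", "CAG"})

    def test_stop_codons_rejected_in_class(self):
        with pytest.raises(CodonError, match="non-sense"):
            CodonClassSpec(class_a={"TAA"}, class_b={"AAG"})

    def test_equal_usage_gives_zero_scores_and_p_one(self):
        prof = rscu_profile("ATG" + "AAAAAG" * 3 + "CAACAG" * 3
                            + "GAAGAG" * 3 + "TAA", "g")
        res = codon_class_enrichment([prof] * 3, [prof] * 3)
        assert res["up_median_score"] == 0.0
        assert res["down_median_score"] == 0.0
        assert res["p"] == 1.0

    def test_separated_scores_exact_p(self):
        def prof(body, gid):
            import dataclasses
            return dataclasses.replace(rscu_profile("ATG" + body + "TAA",
                                                    gid), gene_id=gid)
        up = [prof("AAG" * 6, f"u{i}") for i in range(3)]
        down = [prof("AAA" * 6, f"d{i}") for i in range(3)]
        res = codon_class_enrichment(up, down)
        assert res["down_median_score"] > res["up_median_score"]
        assert res["p"] == pytest.approx(0.1)


class TestLengthBias:
    def test_all_at_reference_median_is_degenerate(self):
        res = length_bias_test([300, 300, 300], [100, 300, 500])
        assert res["n_short"] == 0 and res["n_long"] == 0
        assert res["split_p"] == 1.0 and res["degenerate"]

    def test_all_below_median_sign_test(self):
        ref = np.arange(1, 1002)  # median 501
        res = length_bias_test(np.arange(25) + 1, ref)
        assert res["sign_p"] == pytest.approx(2 * 0.5 ** 25, rel=1e-9)

    def test_too_small_set_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            length_bias_test([100], [100, 200, 300])

    def test_split_counts_reported(self):
        res = length_bias_test([10, 20, 900, 950], np.arange(1, 1000))
        assert res["n_short"] == 2 and res["n_long"] == 2


@given(st.lists(st.integers(0, len(SENSE_CODONS) - 1),
                min_size=5, max_size=120))
def test_family_sum_property_any_cds(body):
    """Sum of RSCU over each observed family always equals family size."""
    seq = "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TGA"
    prof = rscu_profile(seq, "g")
    for aa in prof.family_counts:
        fam = FAMILIES[aa]
        assert sum(prof.rscu[c] for c in fam) == pytest.approx(len(fam))
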