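import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from sexbias.selection import (
    SubstitutionSpectrum,
    TranscriptModel,
    UndefinedRateError,
    annotate_substitution,
    combine_deleteriousness,
    compare_groups_fisher,
    compute_rate,
    enumerate_possible_substitutions,
    enumerate_substitutions,
    maf_bin_distribution,
    per_gene_ratios,
    randomization_test,
    selection_ratios,
)

NT = "ACGT"


def oracle_consequence(cds: str, pos: int, alt: str) -> str:
    """Independent oracle: translate the whole mutant CDS and diff proteins."""
    mutant = cds[: pos - 1] + alt + cds[pos:]
    ref_aa = str(Seq(cds).translate())
    alt_aa = str(Seq(mutant).translate())
    i = (pos - 1) // 3
    a, b = ref_aa[i], alt_aa[i]
    if a == "*" and b == "*":
        return "other"
    if a == "*":
        return "stop-loss"
    if b == "*":
        return "stop-gain"
    return "S" if a == b else "NS"


class TestAnnotation:
    @pytest.mark.parametrize(
        "cds,pos,ref,alt,expected",
        [
            ("ATGTGGTAA", 6, "G", "A", "stop-gain"),  # TGG -> TGA
            ("ATGCTCTAA", 6, "C", "T", "S"),  # CTC -> CTT, Leu
            ("ATGAAATAA", 1, "A", "C", "NS"),  # ATG -> CTG, Met -> Leu
            ("ATGAAATAA", 7, "T", "C", "stop-loss"),  # TAA -> CAA
            ("ATGAAATAA", 9, "A", "G", "other"),  # TAA -> TAG, stop to stop
        ],
    )
    def test_examples(self, cds, pos, ref, alt, expected):
        assert annotate_substitution(cds, pos, ref, alt) == expected

    def test_ref_mismatch_and_bounds(self):
        with pytest.raises(ValueError, match="mismatch"):
            annotate_substitution("ATGTAA", 1, "C", "G")
        with pytest.raises(ValueError, match="outside"):
            annotate_substitution("ATGTAA", 7, "A", "G")
        with pytest.raises(ValueError):
            annotate_substitution("ATGTAA", 1, "A", "A")

    def test_all_576_against_mutant_translation_oracle(self):
        """Every codon x position x alternate matches full-CDS translation diff."""
        for codon in ("".join(c) for c in itertools.product(NT, repeat=3)):
            # embed the codon mid-CDS so frame and indexing are exercised
            cds = "ATG" + codon + "TAA" if codon not in ("TAA", "TAG", "TGA") else "ATGAAA" + codon
            offset = 3 if codon not in ("TAA", "TAG", "TGA") else 6
            for i in range(3):
                ref = codon[i]
                for alt in NT:
                    if alt == ref:
                        continue
                    pos = offset + i + 1
                    got = annotate_substitution(cds, pos, ref, alt)
                    assert got == oracle_consequence(cds, pos, alt), (codon, i, alt)

    def test_per_codon_conservation(self):
        """Every non-stop codon contributes exactly 9 substitutions: S + NS + stop-gain."""
        for codon in ("".join(c) for c in itertools.product(NT, repeat=3)):
            if codon in ("TAA", "TAG", "TGA"):
                continue
            cds = "ATG" + codon + "TAA"
            counts = {"S": 0, "NS": 0, "stop-gain": 0}
            for i in range(3):
                for alt in NT:
                    if alt == codon[i]:
                        continue
                    counts[annotate_substitution(cds, 4 + i, codon[i], alt)] += 1
            assert sum(counts.values()) == 9


class TestSpectrum:
    def test_totals_sum_to_3L(self):
        t = TranscriptModel("g", "autosome", "ATGCTCAAATGGTAA")
        spec = enumerate_possible_substitutions(t, lambda *a: True)
        total = sum(
            spec.possible[k] for k in ("S", "NS", "stop-gain", "stop-loss", "other")
        )
        assert total == 3 * len(t.cds)
        # internal codons only feed S/NS/stop-gain; terminal stop gives 9 more
        assert spec["S"] + spec["NS"] + spec["stop-gain"] == 3 * (len(t.cds) - 3)

    def test_atg_codon_has_no_synonymous(self):
        t = TranscriptModel("g", "autosome", "ATGTGGTAA")
        spec = enumerate_possible_substitutions(t, lambda *a: False)
        # Met and Trp are single-codon amino acids: no synonymous change exists
        assert spec["S"] == 0

    def test_degenerate_labelers(self):
        t = TranscriptModel("g", "autosome", "ATGCTCAAATAA")
        all_del = enumerate_possible_substitutions(t, lambda *a: True)
        none_del = enumerate_possible_substitutions(t, lambda *a: False)
        assert all_del["DNS"] == all_del["NS"]
        assert none_del["DNS"] == 0
        assert none_del["DNS"] <= none_del["NS"]

    def test_invalid_cds_rejected(self):
        with pytest.raises(ValueError):
            TranscriptModel("g", "autosome", "ATGCT")  # not multiple of 3
        with pytest.raises(ValueError):
            TranscriptModel("g", "autosome", "ATGTAACCCTAA")  # internal stop


class TestDeleteriousnessRule:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            ("deleterious", "deleterious", True),
            ("deleterious", "probably-damaging", True),
            ("deleterious", "benign", False),
            ("tolerated", "probably-damaging", False),
            ("tolerated", "benign", False),
            ("deleterious", "possibly-damaging", False),
        ],
    )
    def test_and_combination(self, p1, p2, expected):
        assert combine_deleteriousness(p1, p2) is expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            combine_deleteriousness("damaging", "benign")
        with pytest.raises(ValueError):
            combine_deleteriousness("deleterious", "bad")


class TestRates:
    def test_arithmetic(self):
        assert compute_rate(10, 100) == pytest.approx(0.10)
        assert compute_rate(0, 50) == 0.0

    def test_zero_possible_is_undefined(self):
        with pytest.raises(UndefinedRateError):
            compute_rate(5, 0)

    def test_observed_above_possible_rejected(self):
        with pytest.raises(ValueError):
            compute_rate(11, 10)


def _variants_df(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "cds_pos", "ref", "alt", "maf",
                 "consequence", "predictor1", "predictor2"],
    )


def _spectra(possible_by_gene):
    return {
        g: SubstitutionSpectrum(g, dict(p)) for g, p in possible_by_gene.items()
    }


class TestSelectionRatios:
    def test_pooled_not_mean_of_per_gene(self):
        """The set ratio pools counts; averaging per-gene ratios is different."""
        spectra = _spectra({
            "a": {"S": 10, "NS": 40, "DNS": 20, "stop-gain": 4},
            "b": {"S": 100, "NS": 400, "DNS": 200, "stop-gain": 40},
        })
        rows = (
            [("a", 1, "A", "C", 0.1, "S", "tolerated", "benign")] * 1
            + [("a", 2, "A", "C", 0.1, "NS", "deleterious", "deleterious")] * 4
            + [("b", 1, "A", "C", 0.1, "S", "tolerated", "benign")] * 30
            + [("b", 2, "A", "C", 0.1, "NS", "deleterious", "deleterious")] * 20
        )
        variants = _variants_df(rows)
        res = selection_ratios(["a", "b"], variants, spectra, 0.0, 0.0)
        pooled = (24 / 220) / (31 / 110)
        assert res.dns_ratio == pytest.approx(pooled)
        pg = per_gene_ratios(["a", "b"], variants, spectra)
        mean_of_ratios = pg["dDNS/dS"].mean()
        assert res.dns_ratio != pytest.approx(mean_of_ratios)

    def test_maf_thresholds_strict(self):
        spectra = _spectra({"a": {"S": 10, "DNS": 10, "stop-gain": 10}})
        variants = _variants_df([
            ("a", 1, "A", "C", 0.005, "S", "tolerated", "benign"),  # exactly at threshold
            ("a", 2, "A", "C", 0.006, "S", "tolerated", "benign"),
            ("a", 3, "A", "C", 0.006, "NS", "deleterious", "deleterious"),
            ("a", 4, "A", "C", 0.001, "stop-gain", "tolerated", "benign"),  # at stop threshold
            ("a", 5, "A", "C", 0.002, "stop-gain", "tolerated", "benign"),
        ])
        res = selection_ratios(["a"], variants, spectra)
        # strictly above 0.005: one S, one DNS
        assert res.dns_ratio == pytest.approx((1 / 10) / (1 / 10))
        # strictly above 0.001: two S (0.005 and 0.006), one stop
        assert res.stop_ratio == pytest.approx((1 / 10) / (2 / 10))

    def test_zero_synonymous_flagged_undefined(self):
        spectra = _spectra({"a": {"S": 10, "DNS": 10, "stop-gain": 10}})
        variants = _variants_df(
            [("a", 1, "A", "C", 0.1, "NS", "deleterious", "deleterious")]
        )
        res = selection_ratios(["a"], variants, spectra, 0.0, 0.0)
        assert not res.dns_ratio_defined
        assert np.isnan(res.dns_ratio)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            selection_ratios([], _variants_df([]), {})


class TestRandomization:
    def _toy(self, n_pool=5, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_pool)]
        spectra = _spectra({g: {"S": 20, "DNS": 40, "stop-gain": 6} for g in genes})
        rows = []
        for g in genes:
            for _ in range(int(rng.integers(2, 8))):
                rows.append((g, 1, "A", "C", 0.1, "S", "tolerated", "benign"))
            for _ in range(int(rng.integers(2, 12))):
                rows.append((g, 2, "A", "C", 0.1, "NS", "deleterious", "deleterious"))
            rows.append((g, 3, "A", "C", 0.1, "stop-gain", "tolerated", "benign"))
        return genes, _variants_df(rows), spectra

    def test_exhaustive_matches_brute_force(self):
        genes, variants, spectra = self._toy()
        target = genes[:2]
        res = randomization_test(
            target, genes, variants, spectra, exhaustive=True, maf_dns=0.0, maf_stop=0.0
        )
        # brute force over all C(5,2)=10 subsets
        ratios = []
        for subset in itertools.combinations(genes, 2):
            r = selection_ratios(list(subset), variants, spectra, 0.0, 0.0)
            ratios.append(r.dns_ratio)
        target_ratio = selection_ratios(target, variants, spectra, 0.0, 0.0).dns_ratio
        r_count = sum(1 for x in ratios if x >= target_ratio)
        assert res.dns_p == pytest.approx((r_count + 1) / (len(ratios) + 1))

    def test_extreme_target_p_floor(self):
        genes, variants, spectra = self._toy(n_pool=30, seed=3)
        # make one gene's DNS counts overwhelming and target it
        extra = _variants_df(
            [("g0", 2, "A", "C", 0.1, "NS", "deleterious", "deleterious")] * 40
        )
        variants = pd.concat([variants, extra], ignore_index=True)
        # pool excludes the target gene so no random set can tie with it
        res = randomization_test(
            ["g0"], genes[1:], variants, spectra, n_iter=999, seed=1,
            maf_dns=0.0, maf_stop=0.0,
        )
        assert res.dns_p == pytest.approx(1 / 1000)

    def test_weak_target_p_near_one(self):
        genes, variants, spectra = self._toy(n_pool=30, seed=4)
        # target gene with zero DNS variants: ratio 0, every random set >= it
        spectra["weak"] = SubstitutionSpectrum("weak", {"S": 20, "DNS": 40, "stop-gain": 6})
        extra = _variants_df([("weak", 1, "A", "C", 0.1, "S", "tolerated", "benign")] * 5)
        variants = pd.concat([variants, extra], ignore_index=True)
        res = randomization_test(
            ["weak"], genes, variants, spectra, n_iter=499, seed=2,
            maf_dns=0.0, maf_stop=0.0,
        )
        assert res.dns_p == pytest.approx(1.0)

    def test_pool_smaller_than_target_rejected(self):
        genes, variants, spectra = self._toy()
        with pytest.raises(ValueError):
            randomization_test(genes, genes[:3], variants, spectra, n_iter=10)

    def test_reports_random_set_moments(self):
        genes, variants, spectra = self._toy(n_pool=20, seed=5)
        res = randomization_test(
            genes[:4], genes, variants, spectra, n_iter=200, seed=3,
            maf_dns=0.0, maf_stop=0.0,
        )
        assert res.random_dns_mean is not None and res.random_dns_mean > 0
        assert res.random_dns_std is not None and res.random_dns_std >= 0


class TestFisher:
    def test_identical_groups(self):
        fold, odds, p = compare_groups_fisher(10, 100, 10, 100)
        assert fold == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_possible_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_fisher(0, 0, 5, 10)

    @staticmethod
    def fisher_oracle(a, pa, b, pb):
        """Two-sided exact p by enumerating the hypergeometric support."""
        n, k = pa + pb, a + b
        def pmf(x):
            if x < 0 or x > pa or k - x < 0 or k - x > pb:
                return 0.0
            return comb(pa, x) * comb(pb, k - x) / comb(n, k)
        p_obs = pmf(a)
        return sum(pmf(x) for x in range(k + 1) if pmf(x) <= p_obs * (1 + 1e-9))

    def test_against_enumeration_small_tables(self):
        for pa, pb in [(5, 7), (10, 10), (3, 12)]:
            for a in range(pa + 1):
                for b in range(pb + 1):
                    _, _, p = compare_groups_fisher(a, pa, b, pb)
                    assert p == pytest.approx(self.fisher_oracle(a, pa, b, pb), abs=1e-9)

    def test_fold_change_direction(self):
        fold, _, _ = compare_groups_fisher(20, 100, 10, 100)
        assert fold == pytest.approx(2.0)


class TestMafBins:
    def _setup(self):
        spectra = _spectra({
            "a": {"S": 10, "DNS": 20, "stop-gain": 5},
            "b": {"S": 10, "DNS": 20, "stop-gain": 5},
        })
        variants = _variants_df([
            ("a", 1, "A", "C", 0.0005, "S", "tolerated", "benign"),
            ("a", 2, "A", "C", 0.0005, "NS", "deleterious", "deleterious"),
            ("a", 3, "A", "C", 0.01, "S", "tolerated", "benign"),
            ("b", 1, "A", "C", 0.01, "S", "tolerated", "benign"),
            ("b", 2, "A", "C", 0.01, "NS", "deleterious", "deleterious"),
        ])
        return spectra, variants

    def test_single_bin_equals_unfiltered_per_gene(self):
        spectra, variants = self._setup()
        hist = maf_bin_distribution(["a", "b"], variants, spectra, [0.0, 0.5])
        pg = per_gene_ratios(["a", "b"], variants, spectra, maf_threshold=0.0)
        # gene a: dDNS/dS = (1/20)/(2/10) = 0.25 -> category (0.1, 0.5]
        # gene b: (1/20)/(1/10) = 0.5 -> same category (inclusive upper edge)
        assert pg.at["a", "dDNS/dS"] == pytest.approx(0.25)
        assert pg.at["b", "dDNS/dS"] == pytest.approx(0.5)
        assert hist["dDNS/dS"].iloc[0]["(0.1, 0.5]"] == 2

    def test_bins_partition_variants(self):
        spectra, variants = self._setup()
        hist = maf_bin_distribution(
            ["a", "b"], variants, spectra, [0.0, 0.001, 0.5]
        )
        # every gene appears in every bin exactly once (possibly as undefined)
        assert (hist["dDNS/dS"].sum(axis=1) == 2).all()
        # in the rare bin only gene a has variants; b has no S there -> undefined
        assert hist["dDNS/dS"].loc["(0, 0.001]", "undefined"] == 1

    def test_non_monotone_edges_rejected(self):
        spectra, variants = self._setup()
        with pytest.raises(ValueError):
            maf_bin_distribution(["a"], variants, spectra, [0.1, 0.1])
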