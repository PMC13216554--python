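import itertools
import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given
from hypothesis import strategies as st

from ceekit.popgen import (
    GENETIC_CODE,
    CodonError,
    af_bin,
    classify_variant,
    codon_site_counts,
    count_potential_sites,
    cramers_v,
    decile_stratify,
    dos,
    fixation_index,
    jukes_cantor,
    neigojobori_dnds,
    pn_ps,
    pooled_dnds,
)

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
NONSTOP = [c for c in ALL_CODONS if str(Seq(c).translate()) != "*"]


def brute_site_counts(codon):
    """Independent 9-change enumeration using Biopython translation."""
    aa = str(Seq(codon).translate())
    syn = 0
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                alt = codon[:pos] + b + codon[pos + 1 :]
                if str(Seq(alt).translate()) == aa:
                    syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def brute_pathway_counts(c1, c2):
    """Independent pathway-enumeration oracle (stop-avoiding, with fallback)."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(order, allow_stops):
        nd = sd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if str(Seq(nxt).translate()) == "*" and nxt != c2 and not allow_stops:
                return None
            same = str(Seq(cur).translate()) == str(Seq(nxt).translate())
            if same and str(Seq(cur).translate()) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        return nd, sd

    paths = [w for w in (walk(o, False) for o in itertools.permutations(diffs)) if w]
    if not paths:
        paths = [walk(o, True) for o in itertools.permutations(diffs)]
    return (
        float(np.mean([p[0] for p in paths])),
        float(np.mean([p[1] for p in paths])),
    )


class TestPotentialSites:
    def test_phenylalanine_codon(self):
        sites = count_potential_sites("TTT")
        assert sites.s_sites == pytest.approx(1 / 3)
        assert sites.n_sites == pytest.approx(8 / 3)

    def test_methionine_has_no_synonymous_sites(self):
        sites = count_potential_sites("ATG")
        assert sites.s_sites == 0.0
        assert sites.n_sites == 3.0

    def test_all_codons_conserve_three_sites(self):
        for codon in NONSTOP:
            sites = codon_site_counts(codon)
            s_brute, n_brute = brute_site_counts(codon)
            assert sites.s_sites + sites.n_sites == pytest.approx(3.0)
            assert sites.s_sites == pytest.approx(s_brute), codon
            assert sites.n_sites == pytest.approx(n_brute), codon

    def test_errors(self):
        with pytest.raises(CodonError):
            count_potential_sites("TTTA")
        with pytest.raises(CodonError):
            count_potential_sites("TAATTT")  # internal stop
        with pytest.raises(CodonError):
            count_potential_sites("TTN")
        # terminal stop codon is allowed and contributes nothing
        a = count_potential_sites("TTTTAA")
        b = count_potential_sites("TTT")
        assert a.s_sites == b.s_sites and a.n_sites == b.n_sites


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "cds,codon,pos,ref,alt,expected",
        [
            ("TTT", 0, 2, "T", "C", "synonymous"),   # Phe -> Phe
            ("TTT", 0, 0, "T", "A", "missense"),     # Phe -> Ile
            ("TAC", 0, 2, "C", "A", "nonsense"),     # Tyr -> stop
        ],
    )
    def test_examples(self, cds, codon, pos, ref, alt, expected):
        assert classify_variant(cds, codon, pos, ref, alt) == expected

    def test_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            classify_variant("TTT", 0, 0, "A", "G")

    def test_agreement_with_site_counts(self):
        """Summing the 9 classified changes per codon reproduces (3S, 3N)."""
        for codon in NONSTOP:
            syn = sum(
                classify_variant(codon, 0, pos, codon[pos], b) == "synonymous"
                for pos in range(3)
                for b in BASES
                if b != codon[pos]
            )
            sites = codon_site_counts(codon)
            assert syn == pytest.approx(3 * sites.s_sites)


class TestAfBin:
    @pytest.mark.parametrize(
        "af,expected",
        [
            (0.00005, "ultra_rare"),
            (0.0001, "ultra_rare"),   # inclusive upper edge
            (0.0002, "rare"),
            (0.001, "rare"),
            (0.005, "low_frequency"),
            (0.01, "low_frequency"),
            (0.02, "common"),
            (1.0, "common"),
        ],
    )
    def test_bins(self, af, expected):
        assert af_bin(af) == expected

    def test_domain(self):
        with pytest.raises(ValueError):
            af_bin(0.0)
        with pytest.raises(ValueError):
            af_bin(1.5)


class TestRatios:
    def test_pn_ps(self):
        assert pn_ps(4, 200, 2, 100) == pytest.approx(1.0)
        assert pn_ps(0, 200, 2, 100) == 0.0
        assert pn_ps(4, 200, 0, 100) is None

    @given(
        st.integers(1, 50), st.integers(50, 500),
        st.integers(1, 50), st.integers(50, 500),
        st.integers(2, 10),
    )
    def test_pn_ps_scale_invariance(self, pn, n, ps, s, k):
        assert pn_ps(pn, n, ps, s) == pytest.approx(pn_ps(k * pn, n, k * ps, s))

    def test_dos(self):
        assert dos(2, 2, 1, 3) == pytest.approx(0.25)
        assert dos(3, 3, 2, 2) == pytest.approx(0.0)
        assert dos(0, 0, 1, 1) is None

    def test_fixation_index(self):
        assert fixation_index(1.0, 0.5) == pytest.approx(2.0)
        assert fixation_index(0.7, 0.7) == pytest.approx(1.0)
        assert fixation_index(1.0, 0.0) is None


class TestNeiGojobori:
    def test_identical_sequences(self):
        seq = "ATGTTTGGA"
        d = neigojobori_dnds(seq, seq)
        assert d.nd == 0 and d.sd == 0
        assert d.dn == 0 and d.ds == 0

    def test_single_synonymous_difference(self):
        a = "ATG" + "GGA" * 9 + "TTT"
        b = "ATG" + "GGA" * 9 + "TTC"
        d = neigojobori_dnds(a, b)
        assert d.nd == 0
        assert d.dn == 0
        assert d.sd == 1

    def test_matches_pathway_oracle_on_random_pairs(self, rng):
        for _ in range(50):
            codons_a = [NONSTOP[i] for i in rng.integers(0, len(NONSTOP), 30)]
            codons_b = [
                NONSTOP[rng.integers(0, len(NONSTOP))] if rng.random() < 0.3 else c
                for c in codons_a
            ]
            d = neigojobori_dnds("".join(codons_a), "".join(codons_b))
            nd = sd = 0.0
            for ca, cb in zip(codons_a, codons_b):
                pn, ps = brute_pathway_counts(ca, cb)
                nd += pn
                sd += ps
            assert d.nd == pytest.approx(nd)
            assert d.sd == pytest.approx(sd)

    def test_gapped_codons_skipped(self):
        a = "ATG" + "GGA" * 8 + "---" + "TTT"
        b = "ATG" + "GGA" * 8 + "CCC" + "TTC"
        d = neigojobori_dnds(a, b)
        assert d.n_codons_skipped == 1
        assert d.sd == 1
        assert d.nd == 0

    def test_jukes_cantor_domain(self):
        assert jukes_cantor(0.0) == 0.0
        with pytest.raises(ValueError):
            jukes_cantor(0.8)

    def test_parameter_recovery_on_simulated_divergence(self):
        """Planted dN/dS is recovered within 15% at 1000 codons."""
        from ceekit.simulate import SimConfig, simulate_ortholog_pairs

        cfg = SimConfig(seed=11, n_ortholog_pairs=4, ortholog_codons=1000)
        target = cfg.target_dn / cfg.target_ds
        for pair in simulate_ortholog_pairs(cfg):
            d = neigojobori_dnds(pair["seq_a"], pair["seq_b"])
            assert d.nd == pair["nd_true"]
            assert d.sd == pair["sd_true"]
            assert abs(d.dnds - target) / target < 0.15

    def test_pooled_vs_per_pair(self):
        from ceekit.simulate import SimConfig, simulate_ortholog_pairs

        pairs = simulate_ortholog_pairs(
            SimConfig(seed=3, n_ortholog_pairs=5, ortholog_codons=200)
        )
        pooled = pooled_dnds([(p["seq_a"], p["seq_b"]) for p in pairs])
        assert pooled.nd == sum(p["nd_true"] for p in pairs)
        assert pooled.dnds == pytest.approx(
            np.mean([
                neigojobori_dnds(p["seq_a"], p["seq_b"]).dnds for p in pairs
            ]),
            rel=0.2,
        )


class TestDecilesAndCramersV:
    def test_hundred_elements_make_ten_groups_of_ten(self, rng):
        df = pd.DataFrame({
            "tf_count": rng.integers(0, 100, 100),
            "chrom": "1",
            "start": np.arange(100),
        })
        out = decile_stratify(df, "tf_count")
        assert out["decile"].value_counts().eq(10).all()
        # ranking is monotone in the key across deciles
        means = out.groupby("decile")["tf_count"].mean()
        assert means.is_monotonic_increasing

    def test_identical_spectra_give_zero_v(self):
        table = np.tile([10, 5, 3, 1], (10, 1))
        assert cramers_v(table) == pytest.approx(0.0, abs=1e-12)

    def test_v_matches_hand_computed_chi2(self):
        from scipy import stats

        table = np.array([
            [20, 10, 5, 1], [18, 12, 4, 2], [25, 8, 3, 0], [15, 15, 6, 4],
        ])
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        expected = math.sqrt(chi2 / (table.sum() * (min(table.shape) - 1)))
        assert cramers_v(table) == pytest.approx(expected)

    def test_too_few_elements_rejected(self):
        with pytest.raises(ValueError):
            decile_stratify(pd.DataFrame({"k": [1, 2]}), "k")
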