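"""RSA gene statistics: ranking, hypergeometric tails, quartiles, hit calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from poolscreen import (
    HitThresholds,
    build_gene_stats,
    call_hits,
    gene_quartiles,
    rank_guides,
    rsa_logp,
)
from poolscreen.rsa import _hypergeom_logsf, permutation_null_hits

from oracles import rsa_logp_enum, tail_prob_enum


def _stats(z_by_guide: dict, genes: dict) -> pd.DataFrame:
    frame = pd.DataFrame(
        {"gene": pd.Series(genes), "z": pd.Series(z_by_guide, dtype=float)}
    )
    frame.index.name = "guide_id"
    return frame


class TestRankGuides:
    def test_down_and_up_orders(self):
        stats = _stats({"a": -2.0, "b": 0.0, "c": 1.0}, {"a": "X", "b": "X", "c": "Y"})
        assert rank_guides(stats, "down").tolist() == [1, 2, 3]
        assert rank_guides(stats, "up").tolist() == [3, 2, 1]

    def test_tie_broken_by_guide_id(self):
        stats = _stats({"gB": 0.0, "gA": 0.0}, {"gB": "X", "gA": "Y"})
        ranks = rank_guides(stats, "down")
        assert ranks["gA"] == 1 and ranks["gB"] == 2

    def test_nan_z_rejected(self):
        stats = _stats({"a": np.nan, "b": 1.0}, {"a": "X", "b": "X"})
        with pytest.raises(ValueError, match="non-finite"):
            rank_guides(stats, "down")


class TestRsaLogp:
    @pytest.mark.parametrize(
        "ranks,n,N,expected",
        [
            ((1, 3), 2, 10, np.log10(1 / 15)),  # min(0.2, 8/120)
            ((1,), 1, 10, -1.0),
            ((9, 10), 2, 10, 0.0),  # 9-of-10 draws cannot exclude both guides
        ],
    )
    def test_hand_computed_examples(self, ranks, n, N, expected):
        assert rsa_logp(ranks, n, N) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize(
        "ranks,n,N",
        [((1, 1), 2, 10), ((0, 3), 2, 10), ((3, 11), 2, 10), ((1, 2), 3, 10)],
    )
    def test_invalid_ranks_rejected(self, ranks, n, N):
        with pytest.raises(ValueError):
            rsa_logp(ranks, n, N)

    @given(
        data=st.data(),
        N=st.integers(min_value=2, max_value=30),
    )
    def test_matches_enumeration_oracle(self, data, N):
        n = data.draw(st.integers(min_value=1, max_value=min(4, N)))
        ranks = data.draw(
            st.lists(
                st.integers(min_value=1, max_value=N),
                min_size=n, max_size=n, unique=True,
            )
        )
        assert rsa_logp(ranks, n, N) == pytest.approx(
            rsa_logp_enum(ranks, N), rel=1e-12, abs=1e-12
        )

    def test_tail_matches_scipy(self):
        """Own gammaln tail vs scipy.stats.hypergeom at awkward sizes."""
        from scipy.stats import hypergeom

        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(2, 5000))
            n = int(rng.integers(1, min(8, N) + 1))
            r = int(rng.integers(1, N + 1))
            i = int(rng.integers(1, n + 1))
            ours = float(_hypergeom_logsf([i], N, [n], [r])[0])
            theirs = hypergeom.sf(i - 1, N, n, r)
            assert np.exp(ours) == pytest.approx(theirs, rel=1e-9, abs=1e-300)

    @given(
        N=st.integers(min_value=3, max_value=60),
        data=st.data(),
    )
    def test_monotone_in_rank_improvement(self, N, data):
        """Moving any one guide rank toward 1 never increases P."""
        n = data.draw(st.integers(min_value=1, max_value=min(4, N)))
        ranks = sorted(
            data.draw(
                st.lists(
                    st.integers(min_value=1, max_value=N),
                    min_size=n, max_size=n, unique=True,
                )
            )
        )
        free = sorted(set(range(1, N + 1)) - set(ranks))
        which = data.draw(st.integers(min_value=0, max_value=n - 1))
        better = [f for f in free if f < ranks[which]]
        if not better:
            return
        improved = ranks.copy()
        improved[which] = better[-1]
        assert rsa_logp(improved, n, N) <= rsa_logp(ranks, n, N) + 1e-12


class TestGeneQuartiles:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([-2, -1, 0, 1, 2], (-1.0, 1.0)),
            ([3.5, 3.5, 3.5], (3.5, 3.5)),
            ([7.0], (7.0, 7.0)),
        ],
    )
    def test_linear_interpolation_convention(self, values, expected):
        assert gene_quartiles(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gene_quartiles([])


class TestBuildGeneStats:
    def test_two_gene_toy_exact(self):
        """Gene A's two guides at the depleted extreme; enumeration oracle
        fixes logp_down(A) = log10(min over cutoffs) = log10(1/3)."""
        stats = _stats(
            {"a1": -2.0, "a2": -1.5, "b1": 0.0},
            {"a1": "A", "a2": "A", "b1": "B"},
        )
        genes = build_gene_stats(stats)
        expected_a = rsa_logp_enum([1, 2], 3)
        assert genes.loc["A", "logp_down"] == pytest.approx(expected_a, rel=1e-12)
        assert genes.loc["A", "logp_down"] == pytest.approx(np.log10(1 / 3), rel=1e-12)
        assert genes.loc["A", "logp_down"] < genes.loc["B", "logp_down"]
        assert genes.loc["A", "logp_up"] == pytest.approx(0.0, abs=1e-12)
        assert genes.loc["B", "n_guides"] == 1 and genes.loc["B", "low_confidence"]

    def test_central_guides_carry_no_enrichment(self):
        rng = np.random.default_rng(1)
        z = dict(zip([f"g{i}" for i in range(40)], rng.normal(size=40)))
        med = float(np.median(list(z.values())))
        z.update({"c1": med, "c2": med, "c3": med})
        gene = {g: ("CENTER" if g.startswith("c") else f"G{g}") for g in z}
        genes = build_gene_stats(_stats(z, gene))
        assert genes.loc["CENTER", "logp_down"] > -1
        assert genes.loc["CENTER", "logp_up"] > -1

    def test_direction_duality(self):
        """RSA down on z equals RSA up on -z, gene by gene."""
        rng = np.random.default_rng(5)
        ids = [f"g{i}" for i in range(60)]
        z = dict(zip(ids, rng.normal(size=60)))
        gene = {g: f"G{i // 3}" for i, g in enumerate(ids)}
        down = build_gene_stats(_stats(z, gene))
        flipped = build_gene_stats(_stats({g: -v for g, v in z.items()}, gene))
        np.testing.assert_allclose(down["logp_down"], flipped["logp_up"])
        np.testing.assert_allclose(down["logp_up"], flipped["logp_down"])
        np.testing.assert_allclose(down["q1_z"], -flipped["q3_z"])

    def test_unmapped_guide_rejected(self):
        stats = _stats({"a": 0.1, "b": -0.2}, {"a": "X", "b": None})
        with pytest.raises(ValueError, match="no gene mapping"):
            build_gene_stats(stats)

    def test_permutation_fast_path_matches_full_pipeline(self, small_sim):
        """The table-lookup permutation null reproduces exactly the hit
        counts obtained by rebuilding gene stats on permuted labels."""
        from poolscreen import analyze_sim

        guides, _ = analyze_sim(small_sim)
        z = guides["z"].to_numpy()
        thresholds = HitThresholds(rsa_lenient=-1.0, rsa_stringent=-2.0)
        fast = permutation_null_hits(
            z, 5, thresholds=thresholds, n_permutations=5, seed=42
        )
        rng = np.random.default_rng(42)
        for b in range(5):
            perm = rng.permutation(len(z))
            stats = pd.DataFrame(
                {
                    "gene": np.repeat([f"P{i}" for i in range(len(z) // 5)], 5),
                    "z": z[perm],
                },
                index=[f"g{i:05d}" for i in range(len(z))],
            )
            genes = call_hits(build_gene_stats(stats), thresholds)
            slow = int(genes["hit_class"].str.endswith("stringent").sum())
            assert slow == fast[b]


class TestCallHits:
    def _gene_row(self, **kwargs):
        base = {
            "n_guides": 5, "q1_z": 0.0, "q3_z": 0.0,
            "logp_down": 0.0, "logp_up": 0.0,
        }
        base.update(kwargs)
        return pd.DataFrame([base], index=pd.Index(["G"], name="gene"))

    @pytest.mark.parametrize(
        "row,expected",
        [
            (dict(logp_down=-4.0, q1_z=-1.0), "sensitizer_stringent"),  # inclusive
            (dict(logp_down=-3.5, q1_z=-1.2), "sensitizer_lenient"),
            (dict(logp_down=-3.0, q1_z=-1.0), "sensitizer_lenient"),
            (dict(logp_down=-5.0, q1_z=-0.5), "none"),  # z gate fails
            (dict(logp_up=-5.0, q3_z=0.5), "none"),
            (dict(logp_up=-4.0, q3_z=1.0), "resistance_stringent"),
            (dict(logp_up=-3.2, q3_z=1.5), "resistance_lenient"),
            (dict(logp_down=-2.99, q1_z=-9.0), "none"),  # RSA gate fails
        ],
    )
    def test_gate_semantics(self, row, expected):
        genes = call_hits(self._gene_row(**row))
        assert genes.loc["G", "hit_class"] == expected

    def test_both_directions_takes_smaller_logp(self):
        genes = call_hits(
            self._gene_row(logp_down=-3.5, q1_z=-2.0, logp_up=-4.5, q3_z=2.0)
        )
        assert genes.loc["G", "hit_class"] == "resistance_stringent"
        assert bool(genes.loc["G", "both_directions"])

    def test_stringent_subset_of_lenient(self, small_sim):
        from poolscreen import analyze_sim

        _, genes = analyze_sim(small_sim)
        loose = call_hits(genes, HitThresholds(rsa_stringent=-4.0, rsa_lenient=-3.0))
        stringent = set(
            loose.index[loose["hit_class"].str.endswith("stringent")]
        )
        lenient_universe = set(loose.index[loose["hit_class"] != "none"])
        assert stringent <= lenient_universe
        # tightening the lenient gate to the stringent gate leaves only
        # the stringent calls
        tight = call_hits(genes, HitThresholds(rsa_stringent=-4.0, rsa_lenient=-4.0))
        assert set(tight.index[tight["hit_class"] != "none"]) == stringent

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="rsa_stringent"):
            HitThresholds(rsa_stringent=-3.0, rsa_lenient=-4.0)
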