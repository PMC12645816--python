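"""Over-representation statistics against independent oracles.

The oracles here never call the library code paths they check: exact
rational arithmetic (math.comb + Fraction) and literal subset enumeration
stand in for scipy; a hand-written step-down/step-up stands in for
statsmodels; a 2x2 contingency recomputation stands in for the kappa
formula.
"""

import itertools
import math
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varinet.enrichment import (
    BINOMIAL,
    EnrichmentConfig,
    GeneSet,
    bh_fdr,
    bonferroni_correction,
    enrich,
    group_terms,
    holm_correction,
    kappa_score,
    percent_associated,
    read_gmt,
    read_long_tsv,
    term_pvalue,
    write_gmt,
    write_set_metadata,
)


# ---------------------------------------------------------------------------
# independent oracles


def hypergeom_tail_exact(k, M, n, N) -> Fraction:
    """Upper tail by the closed combinatorial sum, in exact rationals."""
    total = math.comb(N, n)
    return Fraction(
        sum(math.comb(M, j) * math.comb(N - M, n - j) for j in range(k, min(M, n) + 1)),
        total,
    )


def hypergeom_tail_enumerate(k, M, n, N) -> Fraction:
    """Upper tail by literally enumerating every size-n subset of the universe."""
    marked = set(range(M))
    hits = sum(
        1 for subset in itertools.combinations(range(N), n) if len(marked.intersection(subset)) >= k
    )
    return Fraction(hits, math.comb(N, n))


def binom_tail_exact(k, n, M, N) -> Fraction:
    p = Fraction(M, N)
    return sum(
        Fraction(math.comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


def holm_by_hand(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    out = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * pvals[i]))
        out[i] = running
    return out


def bh_by_hand(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    out = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, min(1.0, m * pvals[i] / (rank + 1)))
        out[i] = running
    return out


# ---------------------------------------------------------------------------


class TestPercentAssociated:
    @pytest.mark.parametrize(
        "k,M,expected",
        [
            (4, 5, 80.00),
            (8, 8, 100.00),
            (0, 7, 0.00),
            (6, 53, 11.32),
            (3, 4, 75.00),
            (4, 7, 57.14),
            (14, 44, 31.82),
        ],
    )
    def test_reported_coverage_values(self, k, M, expected):
        assert percent_associated(k, M) == expected

    def test_half_up_rounding(self):
        # 100*1/16 = 6.25 exactly; 100*1/3 = 33.333.. rounds down
        assert percent_associated(1, 16) == 6.25
        assert percent_associated(1, 3) == 33.33

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            percent_associated(5, 4)
        with pytest.raises(ValueError):
            percent_associated(0, 0)

    @given(st.integers(1, 60).flatmap(lambda M: st.tuples(st.integers(0, M), st.just(M))))
    def test_bounds_and_full_coverage(self, kM):
        k, M = kM
        pct = percent_associated(k, M)
        assert 0.0 <= pct <= 100.0
        assert (pct == 100.0) == (k == M)


class TestTermPvalue:
    def test_trivial_cases(self):
        assert term_pvalue(0, 5, 10, 100) == 1.0
        assert term_pvalue(0, 5, 10, 100, BINOMIAL) == 1.0
        assert term_pvalue(4, 4, 4, 4) == 1.0  # certain event

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            term_pvalue(11, 4, 10, 100)  # k > n
        with pytest.raises(ValueError):
            term_pvalue(3, 120, 10, 100)  # M > N

    def test_monotone_decreasing_in_k(self):
        ps = [term_pvalue(k, 8, 20, 100) for k in range(0, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_hypergeometric_matches_exact_rational_sum_small_universes(self):
        rng = random.Random(3)
        for _ in range(300):
            N = rng.randint(2, 20)
            n = rng.randint(1, N)
            M = rng.randint(1, N)
            k = rng.randint(0, min(M, n))
            expected = float(hypergeom_tail_exact(k, M, n, N))
            assert term_pvalue(k, M, n, N) == pytest.approx(expected, abs=1e-12)

    def test_exact_sum_agrees_with_literal_subset_enumeration(self):
        # validates the rational-sum oracle itself against brute enumeration
        for N, n, M, k in [(12, 5, 4, 2), (14, 7, 5, 3), (10, 4, 6, 1), (16, 8, 3, 3)]:
            assert hypergeom_tail_exact(k, M, n, N) == hypergeom_tail_enumerate(
                k, M, n, N
            )
            assert term_pvalue(k, M, n, N) == pytest.approx(
                float(hypergeom_tail_enumerate(k, M, n, N)), abs=1e-12
            )

    def test_binomial_matches_exact_rational_sum(self):
        rng = random.Random(5)
        for _ in range(100):
            N = rng.randint(4, 50)
            n = rng.randint(1, N)
            M = rng.randint(1, N)
            k = rng.randint(0, min(M, n))
            expected = float(binom_tail_exact(k, n, M, N))
            assert term_pvalue(k, M, n, N, BINOMIAL) == pytest.approx(
                expected, abs=1e-12
            )


class TestCorrections:
    def test_holm_single_value_unchanged(self):
        assert holm_correction([0.03]) == [0.03]

    def test_holm_hand_evaluated_pair(self):
        assert holm_correction([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=6))
    def test_holm_matches_hand_stepdown_and_is_dominated_by_bonferroni(self, pvals):
        got = holm_correction(pvals)
        assert got == pytest.approx(holm_by_hand(pvals), abs=1e-12)
        bonf = bonferroni_correction(pvals)
        assert all(h <= b + 1e-12 for h, b in zip(got, bonf))
        assert all(h >= p for h, p in zip(got, pvals))

    def test_bh_trivial_cases(self):
        assert bh_fdr([0.05]) == [0.05]
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_bh_matches_independent_stepup(self):
        rng = random.Random(11)
        for _ in range(50):
            pvals = [round(rng.random(), 4) for _ in range(rng.randint(1, 12))]
            assert bh_fdr(pvals) == pytest.approx(bh_by_hand(pvals), abs=1e-12)


class TestKappa:
    DOMAIN = {f"g{i}" for i in range(12)}

    def test_identical_sets_score_one(self):
        s = {"g0", "g1", "g2"}
        assert kappa_score(s, s, self.DOMAIN) == 1.0
        assert kappa_score(self.DOMAIN, self.DOMAIN, self.DOMAIN) == 1.0  # pe = 1 edge

    def test_disjoint_cover_matches_formula(self):
        domain = {"a", "b", "c", "d"}
        set_a, set_b = {"a", "b"}, {"c", "d"}
        pe = (2 * 2 + 2 * 2) / 16  # both marginals are 2/4
        assert kappa_score(set_a, set_b, domain) == pytest.approx(-pe / (1 - pe))

    def test_matches_contingency_table_recomputation(self):
        rng = random.Random(17)
        domain = sorted(self.DOMAIN)
        for _ in range(100):
            sa = {g for g in domain if rng.random() < 0.4}
            sb = {g for g in domain if rng.random() < 0.4}
            if sa == sb:
                continue
            a = sum(1 for g in domain if g in sa and g in sb)
            b = sum(1 for g in domain if g in sa and g not in sb)
            c = sum(1 for g in domain if g not in sa and g in sb)
            d = sum(1 for g in domain if g not in sa and g not in sb)
            t = len(domain)
            po = (a + d) / t
            pe = ((a + b) * (a + c) + (c + d) * (b + d)) / t**2
            assert kappa_score(sa, sb, set(domain)) == pytest.approx(
                (po - pe) / (1 - pe)
            )

    def test_empty_or_tiny_domain_rejected(self):
        with pytest.raises(ValueError):
            kappa_score(set(), set(), set())
        with pytest.raises(ValueError):
            kappa_score({"a"}, {"a"}, {"a"})


def _geneset(i, members):
    return GeneSet(id=f"S{i}", name=f"set {i}", members=frozenset(members))


class TestGroupTerms:
    def test_single_term_is_its_own_group(self):
        rows = enrich(
            ["A", "B", "C"],
            [_geneset(0, ["A", "B", "C"]), _geneset(1, ["X", "Y", "Z"])],
            EnrichmentConfig(min_hits=3),
        )
        assert len(rows) == 1
        assert rows[0].group_id == "Group00"
        assert rows[0].group_p == rows[0].term_p

    def test_identical_hit_lists_share_a_group(self):
        sets = [
            _geneset(0, ["A", "B", "C", "D"]),
            _geneset(1, ["A", "B", "C", "E"]),
            _geneset(2, ["U", "V", "W"]),
        ]
        rows = enrich(["A", "B", "C", "U", "V", "W"], sets, EnrichmentConfig(min_hits=3))
        by_id = {r.term.id: r.group_id for r in rows}
        assert by_id["S0"] == by_id["S1"] != by_id["S2"]

    def test_planted_three_cluster_fixture_matches_component_oracle(self):
        import networkx as nx

        rng = random.Random(23)
        clusters = [["A", "B", "C", "D"], ["E", "F", "G"], ["H", "I", "J", "K"]]
        sets, query = [], []
        for ci, core in enumerate(clusters):
            query += core
            for j in range(3):
                members = set(core) | {f"pad{ci}{j}{x}" for x in range(j)}
                sets.append(_geneset(f"{ci}_{j}", members))
        rng.shuffle(sets)
        rows = enrich(query, sets, EnrichmentConfig(min_hits=3, kappa_threshold=0.4))
        # brute-force components over pairwise kappa of the hit lists
        g = nx.Graph()
        g.add_nodes_from(r.term.id for r in rows)
        domain = {u.upper() for u in query} & set().union(*(s.members for s in sets))
        for r1 in rows:
            for r2 in rows:
                if r1.term.id < r2.term.id and (
                    kappa_score(set(r1.associated_genes), set(r2.associated_genes), domain)
                    >= 0.4
                ):
                    g.add_edge(r1.term.id, r2.term.id)
        oracle_groups = {
            frozenset(c) for c in nx.connected_components(g)
        }
        got_groups: dict[str, set[str]] = {}
        for r in rows:
            got_groups.setdefault(r.group_id, set()).add(r.term.id)
        assert {frozenset(v) for v in got_groups.values()} == oracle_groups
        assert len(oracle_groups) == 3


class TestEnrich:
    def test_planted_complex_ranks_first_with_full_coverage(self):
        rng = random.Random(41)
        sets = [
            _geneset(i, rng.sample([f"g{j}" for j in range(100)], 6)) for i in range(9)
        ]
        planted = _geneset("planted", ["p1", "p2", "p3", "p4"])
        rows = enrich(list(planted.members), sets + [planted], EnrichmentConfig())
        assert rows[0].term.id == "Splanted"
        assert rows[0].percent_associated == 100.00
        assert rows[0].n_genes == 4

    def test_pathway_mode_filters_alpha_complex_mode_reports_all(self):
        # a term with p ~ 0.07-style above-alpha coverage must survive
        # report-all mode and be dropped by the significant-only mode
        sets = [_geneset(i, [f"u{i}{j}" for j in range(8)]) for i in range(12)]
        # all of S0 (p ~ 2e-8), 3 of S1 (p ~ 0.09), singletons elsewhere
        query = [f"u0{j}" for j in range(8)] + ["u10", "u11", "u12", "u20", "u30", "u40"]
        all_rows = enrich(query, sets, EnrichmentConfig(min_hits=3, report_all=True))
        sig_rows = enrich(query, sets, EnrichmentConfig(min_hits=3, report_all=False))
        assert {r.term.id for r in sig_rows} == {
            r.term.id for r in all_rows if r.term_p <= 0.05
        }
        above = [r for r in all_rows if r.term_p > 0.05]
        assert above and all(not r.significant for r in above)

    def test_min_hits_gate(self):
        sets = [_geneset(0, ["A", "B", "C", "D"])]
        assert enrich(["A", "B"], sets + [_geneset(1, list("XYZ"))], EnrichmentConfig()) == []

    def test_disjoint_query_warns_and_returns_empty(self):
        sets = [_geneset(0, ["A", "B", "C"])]
        with pytest.warns(UserWarning, match="no overlap"):
            assert enrich(["Q1", "Q2"], sets) == []

    def test_corrected_p_dominates_raw_p(self):
        rng = random.Random(53)
        sets = [
            _geneset(i, rng.sample([f"g{j}" for j in range(60)], 8)) for i in range(10)
        ]
        query = rng.sample([f"g{j}" for j in range(60)], 25)
        for row in enrich(query, sets, EnrichmentConfig(min_hits=1)):
            assert 0.0 <= row.term_p <= row.term_p_corrected <= 1.0
            assert row.n_genes == len(row.associated_genes)


class TestNullCalibration:
    def test_empirical_rejection_rate_matches_exact_discrete_null(self):
        """The exact upper-tail test is conservative: under a uniform null
        query the attainable rejection rate at alpha is the discrete tail
        mass below alpha, not alpha itself.  The empirical pooled fraction
        must match that analytic expectation within binomial bounds."""
        from scipy.stats import hypergeom

        from varinet.synthetic import SyntheticConfig, gen_complexome

        cfg = SyntheticConfig(seed=55)
        complexome, universe = gen_complexome(cfg)
        N, query_size, reps, alpha = len(universe), 75, 120, 0.05
        # analytic expectation over terms
        expectations = []
        for gs in complexome:
            ks = list(range(0, gs.size + 1))
            upper = hypergeom.sf([k - 1 for k in ks], N, gs.size, query_size)
            pmf = hypergeom.pmf(ks, N, gs.size, query_size)
            expectations.append(float(pmf[upper <= alpha].sum()))
        expected = sum(expectations) / len(expectations)
        # simulation through term_pvalue
        rng = random.Random(314)
        hits = total = 0
        for _ in range(reps):
            query = set(rng.sample(universe, query_size))
            for gs in complexome:
                p = term_pvalue(len(query & gs.members), gs.size, query_size, N)
                hits += p <= alpha
                total += 1
        frac = hits / total
        half = 3.0 * math.sqrt(expected * (1 - expected) / reps)
        assert abs(frac - expected) <= half


class TestGeneSetIO:
    def test_gmt_round_trip(self, tmp_path):
        sets = [_geneset(i, [f"m{i}{j}" for j in range(4)]) for i in range(3)]
        path = tmp_path / "sets.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert [(s.id, s.members) for s in back] == [
            (s.id, s.members) for s in sets
        ]

    def test_long_tsv_with_metadata_sidecar(self, tmp_path):
        members = tmp_path / "members.tsv"
        members.write_text(
            "set_id\tmember\nCPX-1\tVPS29\nCPX-1\tVPS35\nCPX-1\tVPS26B\nCPX-2\tCHMP5\nCPX-2\tCHMP6\nCPX-2\tCHMP1A\n"
        )
        meta = tmp_path / "meta.tsv"
        meta.write_text(
            "id\tname\tsource_tag\tprocess\n"
            "CPX-1\tRetromer complex\tCOMPLEXES\tretrograde transport\n"
            "CPX-2\tESCRT-III complex\tCOMPLEXES\tmultivesicular body sorting\n"
        )
        sets = read_long_tsv(members, meta)
        assert [s.id for s in sets] == ["CPX-1", "CPX-2"]
        assert sets[1].name == "ESCRT-III complex"
        assert sets[1].process_annotation == "multivesicular body sorting"
        assert sets[0].members == frozenset({"VPS29", "VPS35", "VPS26B"})
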