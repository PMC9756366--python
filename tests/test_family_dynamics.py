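import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polarconverge.family_dynamics import (
    association_scores,
    candidate_mask,
    change_enrichment,
    chi2_2x2,
    composite,
    decompose,
    high_frequency_pfams,
    presence_test,
    presence_tests,
    single_linkage_orthogroups,
    wagner_changes,
    wagner_changes_matrix,
)
from polarconverge.io_formats import node_label, read_newick
from polarconverge.synthetic_data import SimConfig, simulate_panel
from .conftest import make_strain


class TestChi2:
    def test_expected_count_example(self):
        # [[9,1],[3,7]]: ad-bc = 60, chi2 = 20*3600/(10*10*12*8) = 7.5
        chi2, p = chi2_2x2(9, 10, 3, 10)
        assert chi2 == pytest.approx(7.5)
        assert p == pytest.approx(6.2e-3, rel=0.01)

    def test_equal_frequencies_give_p_one(self):
        chi2, p = chi2_2x2(5, 10, 5, 10)
        assert chi2 == 0.0 and p == 1.0

    def test_zero_margin_degenerate(self):
        assert chi2_2x2(0, 10, 0, 10) == (0.0, 1.0)
        assert chi2_2x2(10, 10, 10, 10) == (0.0, 1.0)

    def test_matches_scipy_contingency(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(2, 30, 2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            chi2, p = chi2_2x2(int(k1), int(n1), int(k2), int(n2))
            ref = stats.chi2_contingency(table, correction=False)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_yates_correction_selectable(self):
        chi2_corr, _ = chi2_2x2(9, 10, 3, 10, correction=True)
        ref = stats.chi2_contingency([[9, 1], [3, 7]], correction=True)
        assert chi2_corr == pytest.approx(ref.statistic, abs=1e-10)


def panel_for_presence(k_arctic, n_arctic, k_other, n_other, pfam="PF00001"):
    strains, rows = [], []
    for i in range(n_arctic):
        strains.append(make_strain(f"a{i}", habitat="Arctic"))
        rows.append(1 if i < k_arctic else 0)
    for i in range(n_other):
        strains.append(make_strain(f"o{i}", habitat="Other"))
        rows.append(1 if i < k_other else 0)
    matrix = pd.DataFrame({pfam: rows}, index=[s.strain_id for s in strains])
    return strains, matrix


class TestPresenceTest:
    def test_counts_and_sign(self):
        strains, matrix = panel_for_presence(9, 10, 3, 10)
        result = presence_test(matrix, strains, "PF00001")
        assert (result.k_arctic, result.k_other) == (9, 3)
        assert result.chi2 == pytest.approx(7.5)
        assert result.sign == 1
        assert result.ratio == pytest.approx(3.0)

    def test_symmetric_under_label_swap_with_sign_negation(self, rng):
        for _ in range(20):
            n_a, n_o = rng.integers(2, 10, 2)
            k_a, k_o = rng.integers(0, n_a + 1), rng.integers(0, n_o + 1)
            strains, matrix = panel_for_presence(int(k_a), int(n_a), int(k_o), int(n_o))
            fwd = presence_test(matrix, strains, "PF00001")
            swapped = [
                make_strain(
                    s.strain_id,
                    habitat={"Arctic": "Other", "Other": "Arctic"}[s.habitat],
                )
                for s in strains
            ]
            rev = presence_test(matrix, swapped, "PF00001")
            assert fwd.p == pytest.approx(rev.p, abs=1e-12)
            assert fwd.sign == -rev.sign

    def test_vectorised_matches_single(self, rng):
        strains = [
            make_strain(f"s{i}", habitat="Arctic" if i < 5 else "Other")
            for i in range(15)
        ]
        matrix = pd.DataFrame(
            rng.integers(0, 3, size=(15, 20)),
            index=[s.strain_id for s in strains],
            columns=[f"PF{i:05d}" for i in range(1, 21)],
        )
        table = presence_tests(matrix, strains)
        for pfam in matrix.columns:
            single = presence_test(matrix, strains, pfam)
            assert table.loc[pfam, "p"] == pytest.approx(single.p, abs=1e-12)
            assert table.loc[pfam, "sign"] == single.sign


class TestCandidateFilter:
    def make(self, genome_arctic, transcriptome_arctic):
        strains = [
            make_strain("ga", habitat="Arctic", library_type="genome"),
            make_strain("ta", habitat="Arctic", library_type="transcriptome"),
            make_strain("go", habitat="Other", library_type="genome"),
        ]
        gm = pd.DataFrame({"PF00001": [genome_arctic, 1]}, index=["ga", "go"])
        tm = pd.DataFrame({"PF00001": [transcriptome_arctic]}, index=["ta"])
        return strains, gm, tm

    def test_genomes_only_is_not_candidate(self):
        strains, gm, tm = self.make(3, 0)
        assert not candidate_mask(gm, tm, strains)["PF00001"]

    def test_one_of_each_is_candidate(self):
        strains, gm, tm = self.make(1, 1)
        assert candidate_mask(gm, tm, strains)["PF00001"]

    def test_matches_bruteforce_scan(self, rng):
        strains = [
            make_strain(
                f"s{i}",
                habitat=("Arctic", "Other")[int(rng.integers(2))],
                library_type=("genome", "transcriptome")[i % 2],
            )
            for i in range(10)
        ]
        g_ids = [s.strain_id for s in strains if s.library_type == "genome"]
        t_ids = [s.strain_id for s in strains if s.library_type == "transcriptome"]
        pfams = [f"PF{i:05d}" for i in range(1, 16)]
        gm = pd.DataFrame(rng.integers(0, 2, (len(g_ids), 15)), index=g_ids, columns=pfams)
        tm = pd.DataFrame(rng.integers(0, 2, (len(t_ids), 15)), index=t_ids, columns=pfams)
        mask = candidate_mask(gm, tm, strains)
        habitat = {s.strain_id: s.habitat for s in strains}
        for pfam in pfams:
            expected = any(
                gm.loc[s, pfam] > 0 for s in g_ids if habitat[s] == "Arctic"
            ) and any(tm.loc[s, pfam] > 0 for s in t_ids if habitat[s] == "Arctic")
            assert mask[pfam] == expected


class TestHighFrequency:
    def test_range_boundaries(self):
        matrix = pd.DataFrame(
            {"PFA": [0, 101], "PFB": [0, 100], "PFC": [10, 115]}, index=["s1", "s2"]
        )
        assert high_frequency_pfams(matrix) == {"PFA", "PFC"}

    def test_matches_column_range_oracle(self, rng):
        matrix = pd.DataFrame(rng.integers(0, 200, (8, 30)))
        got = high_frequency_pfams(matrix)
        expected = {
            c for c in matrix.columns if matrix[c].max() - matrix[c].min() > 100
        }
        assert got == expected


class TestDecompose:
    def assignment(self, members):
        return pd.DataFrame(members, columns=["strain_id", "gene_id", "orthogroup_id"])

    def proteins(self, members, carrying):
        return pd.DataFrame(
            [(s, g, (s, g) in carrying) for s, g, _ in members],
            columns=["strain_id", "gene_id", "has_pfam"],
        )

    def test_ten_percent_presence_boundary(self):
        # 100 proteins in one orthogroup, all from one strain
        members = [("s1", f"g{i}", "OG1") for i in range(100)]
        for n_carrying, expected in [(9, False), (10, True)]:
            carrying = {("s1", f"g{i}") for i in range(n_carrying)}
            groups = decompose(
                self.proteins(members, carrying),
                self.assignment(members),
                strain_ids=["s1", "s2"],
            )
            assert groups[0].pfam_presence is expected

    def test_frequency_range_filter(self):
        # ranges 2, 3, 4 against strain universe {s1, s2}: keep > 2
        members = (
            [("s1", f"a{i}", "OGa") for i in range(2)]
            + [("s1", f"b{i}", "OGb") for i in range(3)]
            + [("s1", f"c{i}", "OGc") for i in range(4)]
        )
        groups = decompose(
            self.proteins(members, set()),
            self.assignment(members),
            strain_ids=["s1", "s2"],
        )
        assert [g.orthogroup_id for g in groups] == ["OGb", "OGc"]

    def test_unknown_gene_rejected(self):
        members = [("s1", "g1", "OG1")]
        bad = self.assignment([("s1", "gX", "OG1")])
        with pytest.raises(ValueError, match="unknown genes"):
            decompose(self.proteins(members, set()), bad, strain_ids=["s1"])

    def test_single_linkage_standin_components(self):
        # two tight clusters far apart -> two orthogroups
        aln = {
            "s1|g1": "AAAAAAAAAA",
            "s2|g2": "AAAAAAAAAT",
            "s1|g3": "CCCCCCCCCC",
            "s2|g4": "CCCCCCCCCG",
        }
        table = single_linkage_orthogroups(aln, min_identity=0.5)
        by_gene = dict(zip(table["gene_id"], table["orthogroup_id"]))
        assert by_gene["g1"] == by_gene["g2"]
        assert by_gene["g3"] == by_gene["g4"]
        assert by_gene["g1"] != by_gene["g3"]


def random_binary_newick(rng, labels):
    parts = [f"{l}" for l in labels]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), 2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    return parts[0] + ";"


def bruteforce_min_cost(tree, sizes):
    """Exhaustive minimum total |change| over all integer ancestral states."""
    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    lo, hi = min(sizes.values()), max(sizes.values())
    best = None
    for states in itertools.product(range(lo, hi + 1), repeat=len(internal)):
        assigned = dict(zip((id(n) for n in internal), states))
        for leaf in tree.leaf_node_iter():
            assigned[id(leaf)] = sizes[node_label(leaf)]
        cost = sum(
            abs(assigned[id(n)] - assigned[id(n.parent_node)])
            for n in tree.preorder_node_iter()
            if n.parent_node is not None
        )
        best = cost if best is None else min(best, cost)
    return best


class TestWagnerParsimony:
    def test_constant_leaves_no_changes(self):
        tree = read_newick("((A,B),C);")
        changes = wagner_changes(tree, {"A": 4, "B": 4, "C": 4})
        assert changes.empty

    def test_single_expanded_leaf(self):
        tree = read_newick("((A,B),C);")
        changes = wagner_changes(tree, {"A": 5, "B": 1, "C": 1})
        assert len(changes) == 1
        row = changes.iloc[0]
        assert (row["branch_id"], row["signed_change"]) == ("A", 4)

    def test_total_cost_is_parsimony_minimum(self, rng):
        for trial in range(30):
            n_leaves = int(rng.integers(3, 7))
            labels = [f"L{i}" for i in range(n_leaves)]
            tree = read_newick(random_binary_newick(rng, labels))
            sizes = {l: int(rng.integers(0, 6)) for l in labels}
            changes = wagner_changes(tree, sizes)
            total = int(changes["signed_change"].abs().sum())
            assert total == bruteforce_min_cost(tree, sizes)

    def test_matrix_version_matches_per_family(self, rng):
        labels = [f"L{i}" for i in range(5)]
        tree = read_newick(random_binary_newick(rng, labels))
        sizes = pd.DataFrame(
            rng.integers(0, 8, (5, 10)),
            index=labels,
            columns=[f"PF{i:05d}" for i in range(10)],
        )
        table = wagner_changes_matrix(tree, sizes)
        for fam in sizes.columns:
            single = wagner_changes(tree, sizes[fam].to_dict(), family_id=fam)
            got = table[table["family_id"] == fam].set_index("branch_id")["signed_change"]
            want = single.set_index("branch_id")["signed_change"]
            pd.testing.assert_series_equal(
                got.sort_index(), want.sort_index(), check_names=False
            )

    def test_missing_leaf_size_rejected(self):
        tree = read_newick("((A,B),C);")
        with pytest.raises(ValueError, match="C"):
            wagner_changes(tree, {"A": 1, "B": 2})


class TestChangeEnrichmentAndComposite:
    def strains(self):
        return [make_strain(f"a{i}", habitat="Arctic") for i in range(5)] + [
            make_strain(f"o{i}", habitat="Other") for i in range(5)
        ]

    def test_arctic_biased_expansions_flagged(self):
        strains, matrix = panel_for_presence(5, 5, 0, 5)
        presence = presence_test(matrix, strains, "PF00001")
        changes = pd.DataFrame(
            [("PF00001", s.strain_id, 3) for s in strains if s.habitat == "Arctic"],
            columns=["family_id", "branch_id", "signed_change"],
        )
        enrichment = change_enrichment(changes, strains, "PF00001")
        assert enrichment.exp_arctic == 5 and enrichment.exp_other == 0
        assert enrichment.p_con == 1.0
        score = composite(presence, enrichment, candidate=True)
        assert score.y == pytest.approx(-np.log10(enrichment.p_exp))

    def test_symmetric_events_give_zero_y(self):
        strains = self.strains()
        changes = pd.DataFrame(
            [("PF00001", "a0", 2), ("PF00001", "o0", 2)],
            columns=["family_id", "branch_id", "signed_change"],
        )
        enrichment = change_enrichment(changes, strains, "PF00001")
        _, matrix = panel_for_presence(3, 5, 3, 5)
        presence = presence_test(matrix, strains, "PF00001")
        score = composite(presence, enrichment, candidate=True)
        assert score.y == 0.0
        assert not (score.arctic_expanded or score.arctic_contracted)

    def test_no_events_flagged_no_signal(self):
        strains = self.strains()
        changes = pd.DataFrame(columns=["family_id", "branch_id", "signed_change"])
        enrichment = change_enrichment(changes, strains, "PF00001")
        assert enrichment.no_signal

    def test_log_arithmetic(self):
        # p_exp = 1e-8, p_con = 1 -> y = 8
        strains, matrix = panel_for_presence(5, 5, 0, 5)
        presence = presence_test(matrix, strains, "PF00001")
        from polarconverge.family_dynamics import ChangeEnrichment

        enrichment = ChangeEnrichment(
            pfam="PF00001", exp_arctic=5, exp_other=0, con_arctic=0, con_other=0,
            n_arctic=5, n_other=5, p_exp=1e-8, p_con=1.0,
            internal_expansions=0, internal_contractions=0, no_signal=False,
        )
        score = composite(presence, enrichment, candidate=True)
        assert score.y == pytest.approx(8.0)
        assert score.arctic_expanded

    def test_pvalue_floor_prevents_overflow(self):
        from polarconverge.family_dynamics import ChangeEnrichment

        strains, matrix = panel_for_presence(5, 5, 0, 5)
        presence = presence_test(matrix, strains, "PF00001")
        enrichment = ChangeEnrichment(
            pfam="PF00001", exp_arctic=5, exp_other=0, con_arctic=0, con_other=0,
            n_arctic=5, n_other=5, p_exp=0.0, p_con=1.0,
            internal_expansions=0, internal_contractions=0, no_signal=False,
        )
        score = composite(presence, enrichment, candidate=True)
        assert np.isfinite(score.y) and score.y == pytest.approx(300.0)


class TestAssociationPipeline:
    def test_planted_families_dominate_ranking(self, small_panel):
        strains, matrix, tree, truth = small_panel
        genome_ids = [s.strain_id for s in strains if s.library_type == "genome"]
        transcriptome_ids = [
            s.strain_id for s in strains if s.library_type == "transcriptome"
        ]
        table = association_scores(
            matrix.loc[genome_ids], matrix.loc[transcriptome_ids], strains, tree=tree
        )
        # planted enriched families should lead the presence axis
        top_x = set(table.sort_values("x", ascending=False).head(10).index)
        planted = truth.planted_enriched_pfams | truth.planted_expanded_pfams
        assert len(top_x & planted) >= 8
        # planted expanded families separate cleanly on the expansion axis
        exp = table.index.isin(truth.planted_expanded_pfams)
        background_p90 = table.loc[~exp, "y"].quantile(0.90)
        assert (table.loc[exp, "y"] > background_p90).mean() >= 0.8
        assert table.loc[exp, "y"].mean() > 10 * abs(table.loc[~exp, "y"].mean())

    def test_null_panel_yields_no_associations(self):
        from polarconverge.synthetic_data import null_config

        flagged = total = 0
        for seed in range(5):
            cfg = null_config(SimConfig(seed=seed, n_pfams=500,
                                        n_planted_enriched=10, n_planted_expanded=10))
            strains, matrix, tree, _ = simulate_panel(cfg)
            g = [s.strain_id for s in strains if s.library_type == "genome"]
            t = [s.strain_id for s in strains if s.library_type == "transcriptome"]
            table = association_scores(matrix.loc[g], matrix.loc[t], strains, tree=tree)
            flagged += int(table["arctic_associated"].sum())
            flagged += int(table["arctic_expanded"].sum())
            total += len(table)
        assert flagged / total <= 1e-3

    def test_external_change_table_is_drop_in(self, small_panel):
        strains, matrix, tree, _ = small_panel
        g = [s.strain_id for s in strains if s.library_type == "genome"]
        t = [s.strain_id for s in strains if s.library_type == "transcriptome"]
        changes = wagner_changes_matrix(tree, matrix)
        via_tree = association_scores(matrix.loc[g], matrix.loc[t], strains, tree=tree)
        via_table = association_scores(
            matrix.loc[g], matrix.loc[t], strains, changes=changes
        )
        pd.testing.assert_frame_equal(via_tree, via_table)
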