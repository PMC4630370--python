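"""Generator contracts: determinism, ground-truth bookkeeping, packaged tables."""

import numpy as np
import pytest

from peptarget.itraq_quant import OFF, ON, TIME_POINTS
from peptarget.synthetic_data import (
    TABLE3_THRESHOLDS,
    gen_itraq_experiment,
    gen_network_fixture,
    gen_pulldown_fixture,
    gen_reporter_spectrum,
    load_paper_tables,
)


class TestPulldownGenerator:
    def test_cardinalities_and_flags(self):
        fx = gen_pulldown_fixture(265, 104, 106, seed=1)
        assert len(fx.identified) == 265
        assert len(fx.sticky) == 104
        assert len(fx.central) == 106
        assert fx.sticky <= set(fx.identified)
        assert fx.central <= set(fx.identified) - fx.sticky
        assert set(fx.crapome_counts) <= set(fx.identified)
        assert all(c >= 0 for c in fx.crapome_counts.values())
        assert all(set(s) <= set("ACDEFGHIKLMNPQRSTVWY") for s in fx.sequences.values())

    def test_seeded_determinism(self):
        a = gen_pulldown_fixture(265, 104, 106, seed=1)
        b = gen_pulldown_fixture(265, 104, 106, seed=1)
        assert a == b

    def test_no_flags_case(self):
        fx = gen_pulldown_fixture(10, 0, 0, seed=7)
        assert not fx.sticky and not fx.central and not fx.crapome_counts

    def test_cardinality_violation_rejected(self):
        with pytest.raises(ValueError):
            gen_pulldown_fixture(10, 8, 5, seed=0)


class TestReporterSpectrumGenerator:
    def test_pure_channel_is_template(self, templates):
        obs = gen_reporter_spectrum([1, 0, 0, 0], templates, 0.0, 0)
        assert obs == pytest.approx(templates[0].intensity)

    def test_noiseless_linear_combination(self, templates):
        r = [1.0, 2.0, 1.0, 0.5]
        obs = gen_reporter_spectrum(r, templates, 0.0, 0)
        expected = sum(c * t.intensity for c, t in zip(r, templates))
        assert obs == pytest.approx(expected)

    def test_nonnegative_under_noise_and_deterministic(self, templates):
        a = gen_reporter_spectrum([1, 2, 1, 0.5], templates, 0.5, seed=5)
        b = gen_reporter_spectrum([1, 2, 1, 0.5], templates, 0.5, seed=5)
        assert np.array_equal(a, b)
        assert (a >= 0).all()

    def test_negative_ratio_rejected(self, templates):
        with pytest.raises(ValueError):
            gen_reporter_spectrum([-1, 0, 0, 0], templates, 0.0, 0)


class TestItraqGenerator:
    def test_structure_and_truth_bookkeeping(self):
        fx = gen_itraq_experiment(50, 0.2, 3.0, 2, 0.1, 0.04, 0.04, seed=11)
        assert len(fx.spectra) == 100
        assert set(fx.peptide_map.values()) <= {f"SYN{i:05d}" for i in range(1, 51)}
        for (prot, tp), status in fx.onoff_truth.items():
            if status == "normal":
                assert fx.true_ratio[(prot, tp)] > 0
        # every peptide maps to exactly one protein
        assert len(fx.peptide_map) == 100

    def test_null_experiment_all_ratios_one(self):
        fx = gen_itraq_experiment(5, 0, 1.5, 1, 0, 0, 0, seed=2)
        assert all(v == 1.0 for v in fx.true_ratio.values())
        assert all(s == "normal" for s in fx.onoff_truth.values())

    def test_seeded_determinism(self):
        a = gen_itraq_experiment(20, 0.3, 2.5, 2, 0.2, 0.05, 0.05, seed=9)
        b = gen_itraq_experiment(20, 0.3, 2.5, 2, 0.2, 0.05, 0.05, seed=9)
        assert a.true_ratio == b.true_ratio
        assert a.onoff_truth == b.onoff_truth
        assert all(np.array_equal(a.spectra[p], b.spectra[p]) for p in a.spectra)

    def test_fraction_and_effect_validation(self):
        with pytest.raises(ValueError):
            gen_itraq_experiment(10, 0.6, 3.0, 1, 0.1, 0.3, 0.3, seed=0)
        with pytest.raises(ValueError):
            gen_itraq_experiment(10, 0.1, 0.9, 1, 0.1, seed=0)


class TestNetworkGenerator:
    def test_connected_no_self_loops_no_duplicates(self):
        import networkx as nx

        fx = gen_network_fixture(40, 80, 2, 10, 5, seed=1)
        g = fx.graph()
        assert g.number_of_nodes() == 40
        assert g.number_of_edges() == 80
        assert nx.is_connected(g)
        assert all(u != v for u, v in fx.edges)
        assert len(fx.edges) == len(set(fx.edges))

    def test_terms_induce_connected_subgraphs(self):
        import networkx as nx

        fx = gen_network_fixture(60, 140, 5, 12, 8, seed=3)
        g = fx.graph()
        for members in fx.term2nodes.values():
            assert members <= set(g.nodes)
            assert nx.is_connected(g.subgraph(members))

    def test_placement_ground_truth(self):
        fx = gen_network_fixture(40, 80, 1, 10, 5, seed=1)
        assert len(fx.targets) == 5
        for target, (kind, term) in fx.placement.items():
            members = fx.term2nodes[term]
            if kind == "direct":
                assert target in members
            elif kind == "peripheral":
                assert target not in members
                assert any(
                    (min(target, m), max(target, m)) in set(fx.edges) for m in members
                )
        assert all(0 < a <= 1 for a in fx.targets.values())

    def test_no_targets_gives_zero_score(self):
        from peptarget.netscore import FunctionalSubnetwork, s_net

        fx = gen_network_fixture(40, 80, 1, 10, 0, seed=1)
        term, members = next(iter(fx.term2nodes.items()))
        score = s_net(FunctionalSubnetwork(term, frozenset(members)), {}, fx.graph())
        assert score.s_net == 0.0

    def test_infeasible_sizes_rejected(self):
        with pytest.raises(ValueError):
            gen_network_fixture(10, 4, 1, 5, 2, seed=0)  # fewer edges than a tree
        with pytest.raises(ValueError):
            gen_network_fixture(10, 20, 1, 50, 2, seed=0)  # term larger than graph


class TestPaperTables:
    def test_row_counts(self, paper_tables):
        assert len(paper_tables.table1) == 55
        assert len(paper_tables.table2) == 10
        assert len(paper_tables.table3) == 72

    def test_spot_values(self, paper_tables):
        t1 = paper_tables.table1.set_index("gene")
        assert t1.loc["C1QBP", "empai"] == pytest.approx(1.74)
        assert t1.loc["C1QBP", "score"] == 648
        t2 = paper_tables.table2.set_index("go_id")
        assert t2.loc["GO:0045786", "nodes"] == 37
        assert t2.loc["GO:0045786", "targets"] == 8
        assert t2.loc["GO:0045786", "s_net"] == pytest.approx(0.076)
        t3 = paper_tables.table3.set_index("gene")
        assert list(t3.loc["MCM6", ["fc_40min", "fc_2h", "fc_5h"]]) == [-4.2, -1.1, -2.0]
        assert list(t3.loc["ARVCF", ["fc_40min", "fc_2h", "fc_5h"]]) == ["ON", "ON", "ON"]
        assert t3.loc["CCBL2", "fc_2h"] == "OFF"

    def test_chemical_overlap_column_marks_eight(self, paper_tables):
        assert int(paper_tables.table3["chem_target"].sum()) == 8

    def test_thresholds(self, paper_tables):
        assert paper_tables.thresholds == TABLE3_THRESHOLDS == {
            "40min": 2.6, "2h": 2.6, "5h": 2.4
        }
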