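import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from circatf import (
    StudyConfig,
    classify_regulator_sign,
    nominate_dr_tfs,
    random_tf_resample_test,
    simulate_study,
    ubiquitylation_crosstab,
)


def rhythm_table(flags: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {"feature_id": list(flags), "rhythmic": [bool(v) for v in flags.values()]}
    )


def hypergeom_tail_oracle(k, n_bg, n_bg_pos, n_draw):
    """Exact upper-tail sum of the hypergeometric pmf via binomials."""
    total = math.comb(n_bg, n_draw)
    return sum(
        math.comb(n_bg_pos, i) * math.comb(n_bg - n_bg_pos, n_draw - i)
        for i in range(k, min(n_draw, n_bg_pos) + 1)
    ) / total


class TestNominateDrTfs:
    def _net(self, tf, tgs):
        g = nx.DiGraph()
        for t in tgs:
            g.add_edge(tf, t)
        return g

    def test_enriched_targets_nominated(self):
        tgs = [f"G{i}" for i in range(10)]
        bg = {f"B{i}": (i < 92) for i in range(990)}  # ~10% rhythmic baseline
        bg.update({t: (i < 8) for i, t in enumerate(tgs)})  # 8/10 rhythmic
        out = nominate_dr_tfs(
            rhythm_table({"TF1": True}), rhythm_table(bg), self._net("TF1", tgs)
        )
        row = out.iloc[0]
        assert row.is_dr_tf
        assert row.target_rhythm_p < 1e-6
        assert row.target_rhythm_p == pytest.approx(
            hypergeom_tail_oracle(8, 1000, 100, 10), rel=1e-9
        )

    def test_nonrhythmic_tf_never_nominated(self):
        tgs = ["G1", "G2", "G3", "G4"]
        out = nominate_dr_tfs(
            rhythm_table({"TF1": False}),
            rhythm_table({**{t: True for t in tgs}, **{f"B{i}": False for i in range(50)}}),
            self._net("TF1", tgs),
        )
        assert not out.iloc[0].is_dr_tf

    def test_too_few_targets_flagged(self):
        out = nominate_dr_tfs(
            rhythm_table({"TF1": True}),
            rhythm_table({"G1": True, "G2": True, "B1": False}),
            self._net("TF1", ["G1", "G2"]),
            min_tg=3,
        )
        row = out.iloc[0]
        assert row.insufficient_targets and not row.is_dr_tf

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            nominate_dr_tfs(
                rhythm_table({"TF1": True}), rhythm_table({"G1": True}), nx.DiGraph()
            )


class TestClassifyRegulatorSign:
    def test_exact_activator_repressor(self):
        x = np.sin(np.linspace(0, 4 * np.pi, 16))
        tg = pd.DataFrame({"up": x, "down": -x}).T
        out = classify_regulator_sign(x, tg).set_index("target")
        assert out.loc["up", "label"] == "activator"
        assert out.loc["up", "r"] == pytest.approx(1.0)
        assert out.loc["down", "label"] == "repressor"

    def test_boundary_r_half_unclassified(self):
        # corr((1,2,3), (1,3,2)) = 1/2: at the strict activator boundary
        x = np.array([1.0, 2.0, 3.0])
        out = classify_regulator_sign(x, pd.DataFrame({"tg": [1.0, 3.0, 2.0]}).T)
        assert out.iloc[0].r == pytest.approx(0.5)
        assert out.iloc[0].label == "unclassified"

    def test_zero_variance_flagged(self):
        x = np.arange(16.0)
        out = classify_regulator_sign(x, pd.DataFrame({"tg": np.ones(16)}).T)
        assert out.iloc[0].label == "unclassified" and out.iloc[0].flagged

    def test_sign_counts_conserved_on_study(self, default_bundle):
        from circatf import RunConfig, ibaq_to_fot, zscore_per_cycle
        from circatf.rhythm import jtk_cycle

        b = default_bundle
        cfg = RunConfig(seed=11)
        z_tf = zscore_per_cycle(ibaq_to_fot(b.matrices["tf_dba"]))
        z_tx = zscore_per_cycle(b.matrices["transcriptome"])
        out = nominate_dr_tfs(
            jtk_cycle(z_tf, cfg),
            jtk_cycle(z_tx, cfg),
            b.tf_tg,
            tf_matrix=z_tf,
            tg_matrix=z_tx,
        )
        assert (
            out.n_activated + out.n_repressed + out.n_unclassified == out.n_targets
        ).all()


class TestUbiquitylationCrosstab:
    def _net(self, mapping):
        g = nx.DiGraph()
        for tf, tgs in mapping.items():
            for t in tgs:
                g.add_edge(tf, t)
        return g

    def test_percentage_arithmetic(self):
        tfs = {f"TF{i}": i < 40 for i in range(80)}
        net = self._net({t: [f"G_{t}"] for t in tfs})
        ubi = {"TF0", "TF1"}  # 2 of 40 rhythmic TFs
        ct = ubiquitylation_crosstab(rhythm_table(tfs), net, ubi)
        assert ct.pct_rhythmic_tfs == pytest.approx(5.0)
        assert ct.pct_nonrhythmic_tfs == 0.0

    def test_tg_union_percentage(self):
        # rhythmic TFs A,B with overlapping target sets forming a union of 25
        tg_a = [f"G{i}" for i in range(15)]
        tg_b = [f"G{i}" for i in range(10, 25)]
        net = self._net({"A": tg_a, "B": tg_b})
        ct = ubiquitylation_crosstab(
            rhythm_table({"A": True, "B": True}), net, {"G0", "G20"}
        )
        assert ct.counts["n_tgs_of_rhythmic"] == 25
        assert ct.pct_tgs_of_rhythmic == pytest.approx(8.0)

    def test_empty_denominator_undefined(self):
        net = self._net({"A": ["G1"]})
        ct = ubiquitylation_crosstab(rhythm_table({"A": False}), net, set())
        assert ct.pct_rhythmic_tfs is None
        assert ct.pct_nonrhythmic_tfs == 0.0


class TestResampleTest:
    def _study_net(self, seed=0, boost=1.0):
        b = simulate_study(
            StudyConfig(
                n_tfs=40,
                n_tgs_per_tf=8,
                frac_rhythmic=0.5,
                ubi_rhythmic_tg_boost=boost,
                layers=("tf_dba", "transcriptome"),
                seed=seed,
            )
        )
        return b.tf_tg, b.truth

    def test_all_tfs_gives_p_one(self):
        net, truth = self._study_net()
        res = random_tf_resample_test(net, truth.ubi_set, truth.tf_ids, seed=1)
        assert res["p"] == 1.0

    def test_zero_observed_gives_p_one(self):
        net, truth = self._study_net()
        res = random_tf_resample_test(net, set(), truth.rhythmic_tf_ids, seed=1)
        assert res["observed"] == 0 and res["p"] == 1.0

    def test_small_n_iter_rejected(self):
        net, truth = self._study_net()
        with pytest.raises(ValueError):
            random_tf_resample_test(net, truth.ubi_set, truth.rhythmic_tf_ids, n_iter=50)

    def test_planted_enrichment_detected(self):
        """Targets of rhythmic TFs ubiquitylated at 3x the base rate give a
        small empirical p."""
        net, truth = self._study_net(seed=4, boost=3.0)
        res = random_tf_resample_test(
            net, truth.ubi_set, truth.rhythmic_tf_ids, n_iter=10_000, seed=2
        )
        assert res["p"] < 0.01

    def test_seed_reproducible(self):
        net, truth = self._study_net()
        r1 = random_tf_resample_test(net, truth.ubi_set, truth.rhythmic_tf_ids, seed=5)
        r2 = random_tf_resample_test(net, truth.ubi_set, truth.rhythmic_tf_ids, seed=5)
        assert r1 == r2
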