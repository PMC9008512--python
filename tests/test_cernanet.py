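"""Correlation filters, triplet integration and network accounting."""

import numpy as np
import pandas as pd
import pytest

from cernakit import cernanet
from cernakit._errors import ValidationError
from cernakit.containers import ExpressionMatrix
from cernakit.targets import TargetHit

from _oracles import network_counts_oracle, pearson_oracle, spearman_oracle


def _hit(mir, tgt):
    return TargetHit(mirna_id=mir, transcript_id=tgt, site_start=1,
                     expectation=0.0, alignment=("", "", ""))


def _expr(rows: dict, unit):
    df = pd.DataFrame(rows).T
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    meta = pd.DataFrame(
        {"stage": ["A"] * df.shape[1],
         "replicate": list(range(df.shape[1]))},
        index=pd.Index(df.columns, name="sample_id"))
    return ExpressionMatrix(values=df, unit=unit, sample_meta=meta)


class TestCorrelate:
    def test_monotone_and_linear(self):
        assert cernanet.correlate([1, 2, 3, 4], [10, 20, 30, 40],
                                  "spearman") == pytest.approx(1.0)
        assert cernanet.correlate([1, 2, 3, 4], [10, 20, 30, 40],
                                  "pearson") == pytest.approx(1.0)

    def test_reversal(self):
        assert cernanet.correlate([1, 2, 3, 4], [8, 6, 4, 2],
                                  "spearman") == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        x, y = [1, 2, 2, 4], [3, 1, 5, 7]
        assert cernanet.correlate(x, y, "spearman") == pytest.approx(
            spearman_oracle(x, y), abs=1e-12)

    def test_constant_input_is_undefined(self):
        assert np.isnan(cernanet.correlate([1, 1, 1], [1, 2, 3], "pearson"))

    def test_against_textbook_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(1000):
            x = rng.integers(0, 6, 12).astype(float)   # ties likely
            y = rng.normal(size=12)
            if np.ptp(x) == 0:
                continue
            assert cernanet.correlate(x, y, "spearman") == pytest.approx(
                spearman_oracle(list(x), list(y)), abs=1e-12)
            assert cernanet.correlate(x, y, "pearson") == pytest.approx(
                pearson_oracle(list(x), list(y)), abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValidationError):
            cernanet.correlate([1, 2], [1, 2, 3])
        with pytest.raises(ValidationError):
            cernanet.correlate([1, 2], [1, 2])


class TestAssembleTriplets:
    def test_product_counting(self):
        mir2lnc = [_hit("M", "L1"), _hit("M", "L2")]
        mir2mrna = [_hit("M", "G1"), _hit("M", "G2"), _hit("M", "G3")]
        out = cernanet.assemble_triplets(mir2lnc, mir2mrna)
        assert len(out) == 6
        assert len({(t.lncrna_id, t.mirna_id, t.mrna_id) for t in out}) == 6

    def test_mirna_without_mrna_targets(self):
        assert cernanet.assemble_triplets([_hit("M", "L1")], []) == []

    def test_empty(self):
        assert cernanet.assemble_triplets([], []) == []

    def test_duplicate_hits_deduplicated(self):
        out = cernanet.assemble_triplets(
            [_hit("M", "L1"), _hit("M", "L1")], [_hit("M", "G1")])
        assert len(out) == 1


class TestFilterTriplets:
    def _setup(self, mir_prof, lnc_prof, mrna_prof):
        rna = _expr({"L": lnc_prof, "G": mrna_prof}, "FPKM")
        mir = _expr({"M": mir_prof}, "RPM")
        trip = cernanet.CeRNATriplet("L", "M", "G")
        return trip, mir, rna

    def test_planted_structure_passes(self):
        trip, mir, rna = self._setup(
            [8, 7, 6, 5, 4, 3], [1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7])
        net = cernanet.filter_triplets([trip], mir, rna)
        assert trip.passed and len(net.triplets) == 1

    def test_weak_anticorrelation_fails(self):
        trip, mir, rna = self._setup(
            [5, 3, 6, 4, 7, 5], [1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7])
        cernanet.filter_triplets([trip], mir, rna)
        assert trip.scc_mir_lnc > -0.6 and not trip.passed

    def test_pcc_boundary_is_strict(self):
        """r exactly 0.6 fails the strict > 0.6 rule."""
        rng = np.random.default_rng(0)
        # construct y with exact Pearson r = 0.6 against x (on log2 scale
        # pcc uses log2(x+1), so feed values already on that scale via
        # log_pcc=False)
        x = rng.normal(size=12)
        z = rng.normal(size=12)
        x0 = (x - x.mean()) / x.std()
        z0 = z - z.mean()
        z0 -= x0 * (z0 @ x0) / (x0 @ x0)
        z0 /= z0.std()
        r = 0.6
        y = r * x0 + np.sqrt(1 - r**2) * z0
        assert pearson_oracle(list(x0), list(y)) == pytest.approx(0.6)
        rna = _expr({"L": x0 - x0.min(), "G": y - y.min()}, "FPKM")
        mir = _expr({"M": np.linspace(12, 1, 12)}, "RPM")
        trip = cernanet.CeRNATriplet("L", "M", "G")
        cernanet.filter_triplets([trip], mir, rna, log_pcc=False)
        assert trip.pcc_lnc_mrna == pytest.approx(0.6, abs=1e-9)
        assert not trip.passed

    def test_scc_boundary_is_strict(self):
        """rho exactly -0.6 fails the strict < -0.6 rule."""
        # ranks chosen so Spearman rho = -0.6 exactly: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        x = [1, 2, 3, 4, 5]
        y = [4, 5, 1, 3, 2]
        assert spearman_oracle(x, y) == pytest.approx(-0.6)
        rna = _expr({"L": x, "G": x}, "FPKM")
        mir = _expr({"M": y}, "RPM")
        trip = cernanet.CeRNATriplet("L", "M", "G")
        cernanet.filter_triplets([trip], mir, rna)
        assert trip.scc_mir_lnc == pytest.approx(-0.6, abs=1e-12)
        assert not trip.passed

    def test_constant_member_fails(self):
        trip, mir, rna = self._setup(
            [8, 7, 6, 5, 4, 3], [2, 2, 2, 2, 2, 2], [2, 3, 4, 5, 6, 7])
        cernanet.filter_triplets([trip], mir, rna)
        assert not trip.passed

    def test_missing_member_skipped_with_warning(self):
        trip, mir, rna = self._setup(
            [8, 7, 6, 5, 4, 3], [1, 2, 3, 4, 5, 6], [2, 3, 4, 5, 6, 7])
        ghost = cernanet.CeRNATriplet("L", "M", "nope")
        with pytest.warns(UserWarning, match="nope"):
            net = cernanet.filter_triplets([trip, ghost], mir, rna)
        assert len(net.all_candidates) == 1

    def test_threshold_relaxation_is_monotone(self):
        rng = np.random.default_rng(4)
        rna = _expr({f"L{i}": rng.random(12) for i in range(5)}
                    | {f"G{i}": rng.random(12) for i in range(5)}, "FPKM")
        mir = _expr({f"M{i}": rng.random(12) for i in range(3)}, "RPM")
        trips = [cernanet.CeRNATriplet(f"L{i % 5}", f"M{i % 3}", f"G{i % 5}")
                 for i in range(15)]
        strict = cernanet.filter_triplets(
            [cernanet.CeRNATriplet(t.lncrna_id, t.mirna_id, t.mrna_id)
             for t in trips], mir, rna, thresholds=(-0.4, -0.4, 0.4))
        loose = cernanet.filter_triplets(
            [cernanet.CeRNATriplet(t.lncrna_id, t.mirna_id, t.mrna_id)
             for t in trips], mir, rna, thresholds=(-0.2, -0.2, 0.2))
        key = lambda n: {(t.lncrna_id, t.mirna_id, t.mrna_id)
                         for t in n.triplets}
        assert key(strict) <= key(loose)


class TestNetworkAccounting:
    def _net(self, triples):
        net = cernanet.CeRNANetwork()
        for l, m, g in triples:
            t = cernanet.CeRNATriplet(l, m, g, passed=True)
            net.triplets.append(t)
            net.nodes[l] = "lncRNA"
            net.nodes[m] = "miRNA"
            net.nodes[g] = "mRNA"
            net.edges.add((m, l))
            net.edges.add((m, g))
        return net

    def test_shared_mirna_counting(self):
        s = cernanet.summarize_network(
            self._net([("L1", "M", "G1"), ("L2", "M", "G2")]))
        assert s == {"n_triplets": 2, "n_nodes": 5, "n_lncrna": 2,
                     "n_mirna": 1, "n_mrna": 2, "n_edges": 4}

    def test_single_triplet(self):
        s = cernanet.summarize_network(self._net([("L", "M", "G")]))
        assert s["n_nodes"] == 3 and s["n_edges"] == 2

    def test_empty_network(self):
        s = cernanet.summarize_network(cernanet.CeRNANetwork())
        assert all(v == 0 for v in s.values())

    def test_counts_match_set_construction_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            triples = [(f"L{rng.integers(5)}", f"M{rng.integers(3)}",
                        f"G{rng.integers(5)}")
                       for _ in range(rng.integers(1, 20))]
            s = cernanet.summarize_network(self._net(triples))
            n_nodes, n_edges = network_counts_oracle(triples)
            assert (s["n_nodes"], s["n_edges"]) == (n_nodes, n_edges)

    def test_subnetwork_identity_and_empty(self):
        net = self._net([("L1", "M", "G1"), ("L2", "M", "G2")])
        full = cernanet.subnetwork_by_genes(net, {"G1", "G2"})
        assert len(full.triplets) == 2 and full.nodes == net.nodes
        none = cernanet.subnetwork_by_genes(net, {"GX"})
        assert none.triplets == [] and none.nodes == {}
        with pytest.raises(ValidationError):
            cernanet.subnetwork_by_genes(net, set())

    def test_subnetwork_selects_planted_subset(self, small_ds):
        triples = small_ds.truth.planted_triplets
        net = self._net(triples)
        keep = {g for _, _, g in triples[:2]}
        sub = cernanet.subnetwork_by_genes(net, keep)
        assert {(t.lncrna_id, t.mirna_id, t.mrna_id)
                for t in sub.triplets} == set(triples[:2])

    def test_sif_export(self, tmp_path):
        net = self._net([("L1", "M", "G1")])
        path = tmp_path / "net.sif"
        cernanet.write_sif(net, path)
        lines = sorted(path.read_text().splitlines())
        assert lines == ["M\tmir-lnc\tL1", "M\tmir-mrna\tG1"]
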