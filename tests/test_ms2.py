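"""MS2 matching, merging, cosine networking and pattern search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from metabocompare.chem import MassTolerance
from metabocompare.ms2 import (
    FragmentationPattern,
    MergedSpectrum,
    NetworkParams,
    build_network,
    cosine_score,
    find_patterns,
    match_scans_to_features,
    merge_spectra,
    read_mgf,
    shared_fragments,
    simplify_network,
    write_mgf,
)
from metabocompare.rawdata import RawRun, Spectrum


def ms2_scan(rt, precursor, peaks):
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    return Spectrum(rt=rt, ms_level=2, mz=mz, intensity=inten, precursor_mz=precursor)


def merged(fid, peaks, precursor=None):
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    return MergedSpectrum(fid, mz, inten, np.ones(mz.size, dtype=int), precursor)


def random_spectrum(rng, fid, n_peaks=8, pool=None, precursor=None):
    """Random spectrum; drawing m/z from a shared pool creates related
    spectra. Pool spacing > 2x tolerance keeps matching unambiguous."""
    if pool is None:
        mzs = rng.uniform(80, 600, n_peaks)
    else:
        mzs = rng.choice(pool, size=n_peaks, replace=False)
    inten = rng.uniform(0.05, 1.0, n_peaks)
    return merged(fid, sorted(zip(mzs, inten)), precursor or float(rng.uniform(600, 900)))


class TestScanMatching:
    @pytest.fixture
    def setup(self):
        table = make_table(
            {"a": [1.0, 1.0]}, {"a": "g"}, mz=[185.1183, 185.1215], rt=[300.0, 300.0]
        )
        ms1 = Spectrum(rt=0.0, ms_level=1, mz=[100.0], intensity=[1.0])
        return table, ms1

    def test_assignment_rules(self, setup):
        table, ms1 = setup
        scans = [
            ms2_scan(301.0, 185.1184, [(100.0, 1.0)]),  # inside window -> feature 0
            ms2_scan(370.0, 185.1184, [(100.0, 1.0)]),  # RT outside -> unassigned
        ]
        run = RawRun("a", "g", [ms1] + scans)
        assigned = match_scans_to_features(table, {"a": run}, MassTolerance(20, "ppm"))
        assert len(assigned[0]) == 1 and assigned[0][0].rt == 301.0
        assert len(assigned[1]) == 0

    def test_closest_mz_wins_for_coeluting_features(self, setup):
        table, ms1 = setup
        run = RawRun("a", "g", [ms1, ms2_scan(300.0, 185.1184, [(100.0, 1.0)])])
        assigned = match_scans_to_features(table, {"a": run}, MassTolerance(20, "ppm"))
        assert len(assigned[0]) == 1
        assert len(assigned[1]) == 0


class TestMerging:
    def test_single_scan_identity_normalized(self):
        s = ms2_scan(10.0, 500.0, [(100.0, 200.0), (150.0, 100.0)])
        m = merge_spectra([s])
        np.testing.assert_allclose(m.mz, [100.0, 150.0])
        np.testing.assert_allclose(m.intensity, [1.0, 0.5])

    def test_two_identical_scans_unchanged(self):
        peaks = [(100.0, 1.0), (150.0, 0.5)]
        m1 = merge_spectra([ms2_scan(10.0, 500.0, peaks)])
        m2 = merge_spectra([ms2_scan(10.0, 500.0, peaks), ms2_scan(12.0, 500.0, peaks)])
        np.testing.assert_allclose(m1.mz, m2.mz)
        np.testing.assert_allclose(m1.intensity, m2.intensity)
        assert m2.n_scans == 2

    def test_close_peaks_merge_within_tolerance(self):
        m = merge_spectra(
            [ms2_scan(10.0, 500.0, [(100.000, 1.0)]), ms2_scan(11.0, 500.0, [(100.001, 1.0)])],
            tol=0.002,
        )
        assert len(m) == 1
        assert m.mz[0] == pytest.approx(100.0005, abs=1e-6)

    def test_empty_scan_list_rejected(self):
        with pytest.raises(ValueError):
            merge_spectra([])


class TestCosine:
    def test_identical_spectra_score_one(self):
        rng = np.random.default_rng(2)
        a = random_spectrum(rng, "a")
        cos, n = cosine_score(a, a)
        assert cos == pytest.approx(1.0, abs=1e-12)
        assert n == len(a)

    def test_disjoint_spectra_score_zero(self):
        a = merged("a", [(100.0, 1.0)])
        b = merged("b", [(200.0, 1.0)])
        assert cosine_score(a, b) == (0.0, 0)

    def test_hand_computed_example(self):
        a = merged("a", [(100.0, 1.0), (150.0, 0.5)])
        b = merged("b", [(100.0, 0.5), (150.0, 1.0)])
        cos, n = cosine_score(a, b)
        assert cos == pytest.approx(0.8, abs=1e-12)  # (1*0.5 + 0.5*1) / 1.25
        assert n == 2

    def test_symmetric_and_scale_invariant(self):
        rng = np.random.default_rng(3)
        pool = np.arange(80, 600, 1.7)
        for _ in range(10):
            a = random_spectrum(rng, "a", pool=pool)
            b = random_spectrum(rng, "b", pool=pool)
            ab = cosine_score(a, b)
            ba = cosine_score(b, a)
            assert ab[0] == pytest.approx(ba[0], abs=1e-12)
            # MergedSpectrum renormalizes, so scaling is absorbed on input
            scaled = merged("a2", list(zip(a.mz, a.intensity * 7.3)))
            assert cosine_score(scaled, b)[0] == pytest.approx(ab[0], abs=1e-12)

    def test_matches_matchms_cosine_greedy(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(4)
        pool = np.arange(80, 600, 1.7)  # spacing >> tolerance: unambiguous
        sim = CosineGreedy(tolerance=0.002)
        for _ in range(10):
            a = random_spectrum(rng, "a", pool=pool)
            b = random_spectrum(rng, "b", pool=pool)
            ref = matchms.Spectrum(
                mz=a.mz, intensities=a.intensity, metadata={"precursor_mz": a.precursor_mz}
            )
            qry = matchms.Spectrum(
                mz=b.mz, intensities=b.intensity, metadata={"precursor_mz": b.precursor_mz}
            )
            expected = sim.pair(ref, qry)
            cos, n = cosine_score(a, b)
            assert cos == pytest.approx(float(expected["score"]), abs=1e-9)
            assert n == int(expected["matches"])


class TestNetwork:
    def brute_force_edges(self, spectra, params):
        edges = set()
        for i, j in itertools.combinations(spectra, 2):
            cos, n = cosine_score(spectra[i], spectra[j], params)
            if cos >= params.cosine_threshold and n >= params.min_matched_peaks:
                edges.add(frozenset((i, j)))
        return edges

    def test_edges_match_brute_force(self):
        rng = np.random.default_rng(5)
        pool = np.arange(80, 600, 1.7)
        spectra = {f"f{i}": random_spectrum(rng, f"f{i}", n_peaks=10, pool=pool[:40])
                   for i in range(15)}
        params = NetworkParams(cosine_threshold=0.3, min_matched_peaks=3)
        net = build_network(spectra, params)
        got = {frozenset(e) for e in net.graph.edges}
        assert got == self.brute_force_edges(spectra, params)

    def test_min_matched_peaks_gates_high_cosine(self):
        a = merged("a", [(100.0, 1.0), (150.0, 0.5), (200.0, 0.2)])
        b = merged("b", [(100.0, 1.0), (150.0, 0.5), (200.0, 0.2)])
        net = build_network({"a": a, "b": b}, NetworkParams(min_matched_peaks=6))
        assert net.graph.number_of_edges() == 0

    def test_threshold_zero_connects_sharing_spectra(self):
        a = merged("a", [(100.0, 1.0), (300.0, 0.1)])
        b = merged("b", [(100.0, 1.0), (400.0, 0.1)])
        c = merged("c", [(500.0, 1.0)])
        net = build_network(
            {"a": a, "b": b, "c": c}, NetworkParams(cosine_threshold=0.0, min_matched_peaks=1)
        )
        assert {frozenset(e) for e in net.graph.edges} == {frozenset(("a", "b"))}


class TestSimplify:
    def hub_network(self, n_leaves=12):
        rng = np.random.default_rng(6)
        pool = np.arange(80, 600, 1.7)
        hub = random_spectrum(rng, "hub", n_peaks=30, pool=pool[:60])
        spectra = {"hub": hub}
        for i in range(n_leaves):
            idx = rng.choice(len(hub.mz), 8, replace=False)
            spectra[f"leaf{i}"] = merged(
                f"leaf{i}", list(zip(hub.mz[idx], hub.intensity[idx]))
            )
        return build_network(spectra, NetworkParams(cosine_threshold=0.1, min_matched_peaks=2))

    def test_edge_cap_per_node(self):
        net = self.hub_network()
        assert net.graph.degree["hub"] > 10
        out = simplify_network(net, NetworkParams(max_edges_per_node=10))
        assert max(dict(out.graph.degree).values()) <= 10
        assert out.graph.number_of_edges() <= net.graph.number_of_edges()

    def test_cluster_size_cap(self):
        net = self.hub_network(n_leaves=12)
        out = simplify_network(net, NetworkParams(max_edges_per_node=10, max_cluster_size=5))
        import networkx as nx

        assert all(len(c) <= 5 for c in nx.connected_components(out.graph))

    def test_idempotent_fixed_point(self):
        net = self.hub_network()
        params = NetworkParams(max_edges_per_node=6, max_cluster_size=8)
        once = simplify_network(net, params)
        twice = simplify_network(once, params)
        assert set(once.graph.edges) == set(twice.graph.edges)


class TestPatterns:
    GLEA = FragmentationPattern("glea", fragments=[(333.0592, 0.002)])
    LOSS = FragmentationPattern("formic", losses=[(46.0055, 0.002)])

    def test_fragment_hit(self):
        spec = merged("a", [(333.0592, 1.0), (100.0, 0.2)], precursor=570.2674)
        res = find_patterns({"a": spec}, self.GLEA)
        assert bool(res.loc["a", "hit"])

    def test_neutral_loss_hit(self):
        spec = merged("a", [(139.1128, 0.9)], precursor=185.1183)
        res = find_patterns({"a": spec}, self.LOSS)
        assert bool(res.loc["a", "hit"])

    def test_no_elements_no_hit(self):
        spec = merged("a", [(120.0, 1.0)], precursor=570.0)
        assert not find_patterns({"a": spec}, self.GLEA)["hit"].any()
        assert not find_patterns({"a": spec}, self.LOSS)["hit"].any()

    def test_loss_without_precursor_is_error(self):
        spec = merged("a", [(139.1128, 1.0)], precursor=None)
        with pytest.raises(ValueError):
            find_patterns({"a": spec}, self.LOSS)

    def test_low_intensity_peaks_ignored(self):
        spec = merged(
            "a", [(333.0592, 0.004), (100.0, 1.0)], precursor=570.0
        )
        assert not find_patterns({"a": spec}, self.GLEA)["hit"].any()

    def test_hits_monotone_as_tolerance_shrinks(self):
        rng = np.random.default_rng(8)
        spectra = {
            f"s{i}": merged(f"s{i}", [(333.0592 + rng.normal(0, 0.002), 1.0)], precursor=600.0)
            for i in range(30)
        }
        hits = {}
        for tol in (0.005, 0.002, 0.0005):
            pat = FragmentationPattern("glea", fragments=[(333.0592, tol)])
            res = find_patterns(spectra, pat)
            hits[tol] = set(res[res.hit].index)
        assert hits[0.0005] <= hits[0.002] <= hits[0.005]


class TestSharedFragments:
    def test_conserved_labeling(self):
        a = merged("a", [(333.0592, 1.0), (100.0, 0.5)])
        b = merged("b", [(333.0593, 0.8), (200.0, 0.5)])
        groups = shared_fragments([a, b], tol=0.002)
        conserved = groups[groups.conserved]
        assert len(conserved) == 1
        assert conserved.iloc[0]["mz"] == pytest.approx(333.05925, abs=1e-3)

    def test_disjoint_spectra_share_nothing(self):
        a = merged("a", [(100.0, 1.0)])
        b = merged("b", [(200.0, 1.0)])
        assert not shared_fragments([a, b]).conserved.any()

    def test_duplicated_spectrum_all_conserved(self):
        a = merged("a", [(100.0, 1.0), (200.0, 0.4)])
        groups = shared_fragments([a, a])
        assert groups.conserved.all()


def test_mgf_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    spectra = {f"f{i}": random_spectrum(rng, f"f{i}") for i in range(3)}
    path = tmp_path / "spectra.mgf"
    write_mgf(spectra, path)
    back = read_mgf(path)
    assert set(back) == set(spectra)
    for k in spectra:
        np.testing.assert_allclose(back[k].mz, spectra[k].mz, atol=1e-6)
        assert back[k].precursor_mz == pytest.approx(spectra[k].precursor_mz, abs=1e-6)


def test_pattern_yaml_loading(tmp_path):
    path = tmp_path / "patterns.yaml"
    path.write_text(
        "- name: glea\n  fragments: [[333.0592, 0.002]]\n"
        "- name: formic\n  losses: [[46.0055, 0.002]]\n  min_rel_intensity: 0.05\n"
    )
    pats = FragmentationPattern.from_yaml(path)
    assert [p.name for p in pats] == ["glea", "formic"]
    assert pats[1].losses == [(46.0055, 0.002)]
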