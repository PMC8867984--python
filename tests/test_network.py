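import numpy as np
import pytest

from dropspect.network import (
    MsmsSpectrum,
    annotate,
    build_network,
    export_graph,
    match_fragments,
    read_mgf,
    spectral_cosine,
    write_mgf,
)


def spec(sid, peaks, precursor=500.0, name=None):
    return MsmsSpectrum(spectrum_id=sid, precursor_mz=precursor,
                        peaks=np.array(peaks, dtype=float), name=name)


def brute_force_best_pairing(a, b, tol=0.05):
    """Exhaustive one-to-one pairing oracle: max count, then max weight."""
    cands = [
        (i, j)
        for i in range(a.n_peaks)
        for j in range(b.n_peaks)
        if abs(a.peaks[i, 0] - b.peaks[j, 0]) <= tol
    ]
    best = (0, 0.0)

    def rec(k, used_a, used_b, cnt, w):
        nonlocal best
        best = max(best, (cnt, w))
        if k == len(cands):
            return
        rec(k + 1, used_a, used_b, cnt, w)
        i, j = cands[k]
        if i not in used_a and j not in used_b:
            rec(k + 1, used_a | {i}, used_b | {j}, cnt + 1,
                w + a.peaks[i, 1] * b.peaks[j, 1])

    rec(0, frozenset(), frozenset(), 0, 0.0)
    return best


class TestMgfIO:
    def test_round_trip(self, tmp_path):
        spectra = [
            spec("one", [(100.1234, 5000.0), (200.5, 20000.0)], precursor=515.3329),
            spec("two", [(150.0, 3000.0)], precursor=541.3483, name="serratamolide B"),
        ]
        path = tmp_path / "out.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path, intensity_floor=0)
        assert len(back) == 2
        assert back[0].spectrum_id == "one"
        assert back[1].name == "serratamolide B"
        np.testing.assert_allclose(back[0].peaks, spectra[0].peaks, atol=1e-6)

    def test_intensity_floor_strict(self, tmp_path):
        path = tmp_path / "floor.mgf"
        path.write_text(
            "BEGIN IONS\nTITLE=t\nPEPMASS=500.0\n"
            "100.0 999\n200.0 1000\nEND IONS\n"
        )
        spectra = read_mgf(path, intensity_floor=1000)
        assert spectra[0].n_peaks == 1
        assert spectra[0].peaks[0, 0] == 200.0

    def test_all_peaks_below_floor_drops_spectrum(self, tmp_path):
        path = tmp_path / "empty.mgf"
        path.write_text("BEGIN IONS\nTITLE=t\nPEPMASS=500\n100.0 10\nEND IONS\n")
        assert read_mgf(path, intensity_floor=1000) == []

    def test_malformed_block_reports_line(self, tmp_path):
        path = tmp_path / "bad.mgf"
        path.write_text("BEGIN IONS\nPEPMASS=500\nnot-a-peak\nEND IONS\n")
        with pytest.raises(ValueError, match=":3"):
            read_mgf(path)

    def test_missing_pepmass_rejected(self, tmp_path):
        path = tmp_path / "nopm.mgf"
        path.write_text("BEGIN IONS\n100.0 2000\nEND IONS\n")
        with pytest.raises(ValueError, match="PEPMASS"):
            read_mgf(path)


class TestMatchFragments:
    def test_identical_spectra_fully_matched(self):
        a = spec("a", [(100.0, 1e4), (200.0, 2e4), (300.0, 3e4)])
        assert len(match_fragments(a, a)) == 3

    def test_no_match_outside_tolerance(self):
        a = spec("a", [(100.0, 1e4)])
        b = spec("b", [(101.0, 1e4)])
        assert match_fragments(a, b) == []

    def test_exactly_six_common_masses(self):
        rng = np.random.default_rng(11)
        common = np.linspace(100, 400, 6)
        a = spec("a", list(zip(np.concatenate([common, [450.0, 460.0, 470.0, 480.0]]),
                               rng.uniform(2e3, 1e5, 10))))
        b = spec("b", list(zip(np.concatenate([common, [500.0, 510.0, 520.0, 530.0]]),
                               rng.uniform(2e3, 1e5, 10))))
        assert len(match_fragments(a, b)) == 6

    def test_greedy_equals_exhaustive_on_ambiguous_instances(self):
        # peaks drawn from a coarse mass alphabet so one-to-one assignment
        # is genuinely ambiguous
        rng = np.random.default_rng(123)
        alphabet = np.arange(100, 101.6, 0.2)
        for _ in range(30):
            a = spec("a", list(zip(rng.choice(alphabet, 6), rng.uniform(1e3, 1e5, 6))))
            b = spec("b", list(zip(rng.choice(alphabet, 6), rng.uniform(1e3, 1e5, 6))))
            pairs = match_fragments(a, b)
            w = sum(a.peaks[i, 1] * b.peaks[j, 1] for i, j in pairs)
            best_cnt, best_w = brute_force_best_pairing(a, b)
            assert len(pairs) == best_cnt
            assert w == pytest.approx(best_w)

    def test_precursor_shift_links_homologues(self):
        a = spec("a", [(100.0, 1e4), (200.0, 1e4)], precursor=500.0)
        b = spec("b", [(114.01565, 1e4), (214.01565, 1e4)], precursor=514.01565)
        assert match_fragments(a, b) == []
        assert len(match_fragments(a, b, precursor_shift=True)) == 2


class TestSpectralCosine:
    def test_self_cosine_is_one(self):
        a = spec("a", [(100.0, 5e3), (250.0, 9e4), (300.0, 1.2e4)])
        cos, matched = spectral_cosine(a, a)
        assert cos == pytest.approx(1.0, abs=1e-12)
        assert matched == a.n_peaks

    def test_disjoint_is_zero(self):
        a = spec("a", [(100.0, 1e4)])
        b = spec("b", [(300.0, 1e4)])
        cos, matched = spectral_cosine(a, b)
        assert cos == 0.0 and matched == 0

    def test_two_of_three_equal_intensity(self):
        a = spec("a", [(100.0, 1e4), (200.0, 1e4), (300.0, 1e4)])
        b = spec("b", [(100.0, 1e4), (200.0, 1e4), (400.0, 1e4)])
        cos, matched = spectral_cosine(a, b)
        assert cos == pytest.approx(2 / 3, abs=1e-9)
        assert matched == 2

    def test_symmetry(self, spectral_family):
        family, background, _ = spectral_family
        for a, b in zip(family[:3], family[1:4]):
            ca, _ = spectral_cosine(a, b)
            cb, _ = spectral_cosine(b, a)
            assert abs(ca - cb) < 1e-12

    def test_empty_rejected(self):
        a = spec("a", [(100.0, 1e4)])
        b = MsmsSpectrum("b", 500.0, np.empty((0, 2)))
        with pytest.raises(ValueError):
            spectral_cosine(a, b)


class TestBuildNetwork:
    def test_rule_conjunction(self):
        # 5 shared high-intensity peaks: high cosine but too few fragments
        shared = [(100.0 + 30 * i, 5e4) for i in range(5)]
        a = spec("a", shared + [(400.0, 2e3)])
        b = spec("b", shared + [(450.0, 2e3)])
        cos, matched = spectral_cosine(a, b)
        assert cos > 0.7 and matched == 5
        net = build_network([a, b], cosine_cut=0.7, min_matched=6)
        assert net.n_edges == 0
        net = build_network([a, b], cosine_cut=0.7, min_matched=5)
        assert net.n_edges == 1

    def test_family_recovery(self, spectral_family):
        family, background, truth = spectral_family
        net = build_network(family + background, cosine_cut=0.7, min_matched=6)
        comps = sorted(net.components(), key=len)
        assert len(comps[-1]) == 7
        assert comps[-1] == set(truth)
        assert all(len(c) == 1 for c in comps[:-1])

    def test_edge_count_monotone_in_cuts(self, spectral_family):
        family, background, _ = spectral_family
        spectra = family + background
        edges_by_cos = [
            build_network(spectra, cosine_cut=c, min_matched=1).n_edges
            for c in (0.0, 0.3, 0.6, 0.9)
        ]
        assert edges_by_cos == sorted(edges_by_cos, reverse=True)
        edges_by_matched = [
            build_network(spectra, cosine_cut=0.1, min_matched=m).n_edges
            for m in (1, 4, 8, 12)
        ]
        assert edges_by_matched == sorted(edges_by_matched, reverse=True)

    def test_isolated_nodes_flagged(self):
        a = spec("a", [(100.0, 1e4)])
        b = spec("b", [(900.0, 1e4)])
        net = build_network([a, b])
        assert net.graph.nodes["a"]["isolated"]


class TestAnnotate:
    def test_identical_library_spectrum_annotates(self, spectral_family):
        family, _, _ = spectral_family
        lib = [
            MsmsSpectrum("lib1", family[0].precursor_mz, family[0].peaks,
                         name="serratamolide A")
        ]
        net = build_network(family)
        net = annotate(net, family, lib)
        assert net.graph.nodes[family[0].spectrum_id]["annotation"] == "serratamolide A"

    def test_empty_library_no_change(self, spectral_family):
        family, _, _ = spectral_family
        net = build_network(family)
        net2 = annotate(net, family, [])
        assert all("annotation" not in d for _, d in net2.graph.nodes(data=True))

    def test_tie_reports_both(self):
        a = spec("a", [(100.0 + 20 * i, 1e4) for i in range(8)])
        lib = [
            MsmsSpectrum("l1", 500.0, a.peaks, name="compound X"),
            MsmsSpectrum("l2", 500.0, a.peaks, name="compound Y"),
        ]
        net = annotate(build_network([a]), [a], lib)
        assert net.graph.nodes["a"]["annotation"] == "compound X;compound Y"


class TestExport:
    def test_graphml_round_trip(self, tmp_path, spectral_family):
        import networkx as nx

        family, background, _ = spectral_family
        net = build_network(family + background)
        path = tmp_path / "net.graphml"
        export_graph(net, path, fmt="graphml")
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == net.n_nodes
        assert back.number_of_edges() == net.n_edges
        assert net.n_edges >= 6  # 7-member family is densely connected

    def test_empty_network_exports(self, tmp_path):
        net = build_network([spec("a", [(100.0, 1e4)])])
        path = tmp_path / "empty.tsv"
        export_graph(net, path, fmt="edge-list")
        assert path.read_text().startswith("source\ttarget")

    def test_unsupported_format(self, tmp_path):
        net = build_network([spec("a", [(100.0, 1e4)])])
        with pytest.raises(ValueError):
            export_graph(net, tmp_path / "x", fmt="gexf")
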