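"""Spectral similarity, networking and annotation behaviour."""

import numpy as np
import pytest

from _oracles import (
    brute_force_mutual_topk,
    is_conflict_free,
    optimal_assignment_score,
    random_spectrum,
)
from cyanoprospect.specnet import (
    FragmentSpectrum,
    NetworkParams,
    SpectralEdge,
    analog_search,
    build_network,
    candidate_edges,
    export_graphml,
    genus_intensity,
    library_search,
    modified_cosine,
    preprocess,
    read_mgf,
    topk_mutual_filter,
    write_mgf,
)
from cyanoprospect.synthetic_data import (
    SimulationConfig,
    SpectraSimConfig,
    shift_analog,
    simulate_spectra,
)


def spec(fid, precursor, peaks):
    mz, intensity = zip(*peaks)
    return FragmentSpectrum(feature_id=fid, precursor_mz=precursor,
                            mz=np.array(mz), intensity=np.array(intensity))


def norm(s):
    return preprocess(s, precursor_window=0.0, intensity_scale="none")


# ---------------------------------------------------------------------------
# MGF I/O


def test_mgf_single_block_fixture(tmp_path):
    path = tmp_path / "one.mgf"
    path.write_text(
        "BEGIN IONS\nPEPMASS=400.25 12345.0\nCHARGE=1+\nRTINSECONDS=90\n"
        "FEATURE_ID=7\n100.1 10.0\n200.2 20.0\nEND IONS\n"
    )
    (s,) = read_mgf(path)
    assert s.feature_id == "7"
    assert s.precursor_mz == pytest.approx(400.25)
    assert s.rt == pytest.approx(1.5)
    assert s.peaks == [(100.1, 10.0), (200.2, 20.0)]


def test_mgf_round_trip_50_spectra(tmp_path, sim_config):
    spectra, _, _ = simulate_spectra(sim_config)
    extra, _, _ = simulate_spectra(SpectraSimConfig(n_families=4, n_noise_spectra=0), seed=5)
    spectra = (spectra + extra)[:50]
    path = tmp_path / "round.mgf"
    write_mgf(spectra, path)
    back = read_mgf(path)
    assert len(back) == len(spectra)
    for orig, rec in zip(spectra, back):
        assert rec.feature_id == orig.feature_id
        assert rec.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-4)
        assert rec.rt == pytest.approx(orig.rt, abs=1e-4)
        assert rec.mz == pytest.approx(orig.mz, abs=1e-4)
        assert rec.intensity == pytest.approx(orig.intensity, rel=1e-3)


def test_mgf_missing_pepmass_names_block(tmp_path):
    path = tmp_path / "bad.mgf"
    path.write_text(
        "BEGIN IONS\nPEPMASS=400.0\n100.0 1.0\nEND IONS\n"
        "BEGIN IONS\nCHARGE=1+\n100.0 1.0\nEND IONS\n"
    )
    with pytest.raises(ValueError, match="block 2"):
        read_mgf(path)


def test_mgf_malformed_peak_line_is_an_error(tmp_path):
    path = tmp_path / "bad.mgf"
    path.write_text("BEGIN IONS\nPEPMASS=400.0\n100.0 oops\nEND IONS\n")
    with pytest.raises(ValueError, match="malformed"):
        read_mgf(path)


def test_mgf_missing_feature_id_synthesized_with_warning(tmp_path, caplog):
    path = tmp_path / "noid.mgf"
    path.write_text("BEGIN IONS\nPEPMASS=400.0\n100.0 1.0\nEND IONS\n")
    with caplog.at_level("WARNING"):
        (s,) = read_mgf(path)
    assert s.feature_id == "feature_1"
    assert "FEATURE_ID" in caplog.text


# ---------------------------------------------------------------------------
# preprocessing


def test_preprocess_single_peak_normalizes_to_one():
    s = preprocess(spec("a", 400.0, [(100.0, 123.0)]))
    assert s.intensity == pytest.approx([1.0])


def test_preprocess_two_equal_peaks_sqrt_scale():
    s = preprocess(spec("a", 400.0, [(100.0, 4.0), (200.0, 4.0)]))
    assert s.intensity == pytest.approx([1 / np.sqrt(2)] * 2)


def test_preprocess_removes_precursor_window_peaks():
    s = preprocess(spec("a", 400.0, [(399.0, 5.0), (100.0, 5.0)]), precursor_window=17.0)
    assert s.mz.tolist() == [100.0]
    assert preprocess(spec("a", 400.0, [(399.0, 5.0)]), precursor_window=17.0) is None


def test_preprocess_caps_peak_count():
    peaks = [(50.0 + i, 1.0 + i) for i in range(30)]
    s = preprocess(spec("a", 900.0, peaks), max_peaks=10)
    assert s.n_peaks == 10
    assert s.mz.tolist() == [float(70 + i) for i in range(10)]  # keeps most intense


# ---------------------------------------------------------------------------
# modified cosine


def test_self_similarity_is_one():
    s = preprocess(spec("a", 400.0, [(100.0, 3.0), (150.0, 1.0), (300.0, 2.0)]))
    score, n = modified_cosine(s, s)
    assert score == pytest.approx(1.0) and n == 3


def test_disjoint_spectra_score_zero():
    a = norm(spec("a", 400.0, [(100.0, 1.0), (150.0, 1.0)]))
    b = norm(spec("b", 400.0, [(120.0, 1.0), (180.0, 1.0)]))
    assert modified_cosine(a, b) == (0.0, 0)


def test_precursor_shift_matching():
    a = norm(spec("a", 400.0, [(100.0, 1.0), (300.0, 1.0)]))
    b = norm(spec("b", 414.0, [(114.0, 1.0), (314.0, 1.0)]))
    score, n = modified_cosine(a, b, allow_shift=True)
    assert score == pytest.approx(1.0) and n == 2
    score_ns, n_ns = modified_cosine(a, b, allow_shift=False)
    assert score_ns == 0.0 and n_ns == 0


def test_modified_cosine_symmetric_and_bounded(rng):
    for _ in range(30):
        a = random_spectrum(rng, int(rng.integers(2, 9)), "a")
        b = random_spectrum(rng, int(rng.integers(2, 9)), "b")
        ab = modified_cosine(a, b, frag_tol=0.5)
        ba = modified_cosine(b, a, frag_tol=0.5)
        assert ab == pytest.approx(ba)
        assert 0.0 <= ab[0] <= 1.0


def test_greedy_never_beats_optimal_assignment(rng):
    for _ in range(60):
        a = random_spectrum(rng, int(rng.integers(2, 7)), "a")
        b = random_spectrum(rng, int(rng.integers(2, 7)), "b")
        tol = float(rng.choice([0.02, 1.0, 10.0]))
        score, _ = modified_cosine(a, b, frag_tol=tol)
        optimal = optimal_assignment_score(a, b, tol, True)
        assert score <= optimal + 1e-9
        if is_conflict_free(a, b, tol, True):
            assert score == pytest.approx(optimal)


def test_modified_cosine_agrees_with_matchms_on_conflict_free_pairs(rng):
    matchms = pytest.importorskip("matchms")
    from matchms.similarity import ModifiedCosine

    mc = ModifiedCosine(tolerance=0.02)
    for k in range(20):
        base = np.sort(rng.choice(np.arange(60.0, 350.0, 5.0), size=8, replace=False))
        ia = rng.uniform(0.2, 1.0, 8)
        # b shares 5 peaks, has 3 new ones far from a's grid, shifted precursor
        keep = rng.choice(8, 5, replace=False)
        mzb = np.concatenate([base[keep], base[rng.choice(8, 3, replace=False)] + 2.5])
        ib = rng.uniform(0.2, 1.0, 8)
        a = FragmentSpectrum("a", 400.0, base, ia)
        b = FragmentSpectrum("b", 402.5, mzb, ib)
        mine = modified_cosine(norm(a), norm(b), frag_tol=0.02)[0]
        theirs = mc.pair(
            matchms.Spectrum(mz=a.mz, intensities=a.intensity,
                             metadata={"precursor_mz": a.precursor_mz}),
            matchms.Spectrum(mz=b.mz, intensities=b.intensity,
                             metadata={"precursor_mz": b.precursor_mz}),
        )
        assert mine == pytest.approx(float(theirs["score"]), abs=1e-7)


def test_frag_tol_must_be_positive():
    a = norm(spec("a", 400.0, [(100.0, 1.0)]))
    with pytest.raises(ValueError):
        modified_cosine(a, a, frag_tol=0.0)


# ---------------------------------------------------------------------------
# edges and pruning


def _identical_pair(n_peaks):
    peaks = [(60.0 + 10 * i, 1.0) for i in range(n_peaks)]
    return [norm(spec("a", 500.0, peaks)), norm(spec("b", 500.0, peaks))]


def test_candidate_edges_identical_ten_peak_spectra():
    (edge,) = candidate_edges(_identical_pair(10))
    assert edge.score == pytest.approx(1.0) and edge.n_matched == 10


def test_candidate_edges_five_peaks_fail_matched_floor():
    assert candidate_edges(_identical_pair(5)) == []  # >6 matched required


def test_topk_star_keeps_ten_best_leaves():
    edges = [SpectralEdge("hub", f"leaf{i:02d}", 0.99 - 0.01 * i, 8, 0.0)
             for i in range(15)]
    kept = topk_mutual_filter(edges, k=10)
    assert {e.v for e in kept} == {f"leaf{i:02d}" for i in range(10)}
    assert {e.key for e in kept} == brute_force_mutual_topk(edges, 10)


def test_topk_leaves_symmetric_clique_unchanged():
    edges = [SpectralEdge("a", "b", 0.9, 8, 0.0), SpectralEdge("a", "c", 0.9, 8, 0.0),
             SpectralEdge("b", "c", 0.9, 8, 0.0)]
    for k in (2, 5):
        assert {e.key for e in topk_mutual_filter(edges, k)} == {e.key for e in edges}
    with pytest.raises(ValueError):
        topk_mutual_filter(edges, k=0)


def test_topk_matches_brute_force_on_random_graphs(rng):
    nodes = [f"n{i}" for i in range(12)]
    for trial in range(10):
        edges = []
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                if rng.random() < 0.4:
                    edges.append(SpectralEdge(u, v, float(rng.uniform(0.7, 1.0)), 8, 0.0))
        k = int(rng.integers(1, 6))
        assert {e.key for e in topk_mutual_filter(edges, k)} == \
            brute_force_mutual_topk(edges, k)


def test_build_network_recovers_two_planted_families():
    cfg = SpectraSimConfig(n_families=2, spectra_per_family=5, n_noise_spectra=3)
    spectra, _, truth = simulate_spectra(cfg, seed=4)
    net = build_network(spectra)
    assert len(net.clusters) == 2 and len(net.singletons) == 3
    fam = dict(zip(truth.feature_id, truth.family))
    for cluster in net.clusters:
        assert len({fam[f] for f in cluster}) == 1


def test_build_network_cluster_partition_and_determinism(sim_config):
    spectra, _, _ = simulate_spectra(sim_config)
    net1 = build_network(spectra)
    net2 = build_network(spectra)
    assert [sorted(c) for c in net1.clusters] == [sorted(c) for c in net2.clusters]
    assert [e.key for e in net1.edges] == [e.key for e in net2.edges]
    covered = set().union(*net1.clusters) if net1.clusters else set()
    assert all(len(c) >= 2 for c in net1.clusters)
    assert covered | net1.singletons == set(net1.spectra)
    assert covered & net1.singletons == set()


def test_all_dissimilar_spectra_are_singletons(rng):
    spectra = [random_spectrum(rng, 8, f"s{i}", precursor_mz=300.0 + 170 * i)
               for i in range(4)]
    net = build_network(spectra)
    assert net.clusters == [] and len(net.singletons) == 4


# ---------------------------------------------------------------------------
# library annotation


def _library_pair():
    peaks = [(60.0 + 15 * i, float(i + 1)) for i in range(10)]
    query = spec("q1", 500.0, peaks)
    return query, [("compound_x", spec("lib1", 500.0, peaks))]


def test_strict_search_finds_self():
    query, library = _library_pair()
    (hit,) = library_search([query], library)
    assert hit.library_name == "compound_x"
    assert hit.score == pytest.approx(1.0)
    assert hit.precursor_delta == pytest.approx(0.0)
    assert hit.match_type == "strict"


def test_strict_search_respects_precursor_tolerance():
    query, library = _library_pair()
    far = FragmentSpectrum("q2", query.precursor_mz + 50.0, query.mz, query.intensity)
    assert library_search([far], library) == []


def test_analog_search_recovers_mass_shift():
    query, library = _library_pair()
    analog = shift_analog(query, delta=57.02, fraction=0.5)
    (hit,) = analog_search([analog], library)
    assert hit.match_type == "analog"
    assert abs(hit.precursor_delta - 57.02) <= 0.02
    assert hit.n_matched >= 6 and hit.score > 0.7


def test_analog_search_excludes_strict_and_far_deltas():
    query, library = _library_pair()
    assert analog_search([query], library) == []  # delta 0 is not an analog
    far = shift_analog(query, delta=150.0)
    assert analog_search([far], library, max_delta=100.0) == []


# ---------------------------------------------------------------------------
# genus mapping and export


def _network_with_intensities():
    peaks = [(60.0 + 10 * i, 1.0) for i in range(8)]
    a = spec("f1", 500.0, peaks)
    a.sample_intensities = {"s1": 6.0, "s2": 0.0, "s3": 3.0}
    b = spec("f2", 800.0, [(p + 3, i) for p, i in peaks])
    b.sample_intensities = {"s1": 4.0, "s2": 2.0, "s3": 1.0}
    return build_network([a, b])


def test_genus_intensity_means_match_hand_computation():
    net = _network_with_intensities()
    mapping = {"s1": "Lyngbya", "s2": "Lyngbya", "s3": "Scytonema"}
    profile = genus_intensity(net, mapping)
    assert profile.frame.at["f1", "Lyngbya"] == pytest.approx(3.0)  # (6+0)/2
    assert profile.frame.at["f1", "Scytonema"] == pytest.approx(3.0)
    assert profile.dominant["f1"] == "Lyngbya"  # lexicographic tie-break
    assert "f1" in profile.ties
    assert profile.frame.at["f2", "Lyngbya"] == pytest.approx(3.0)  # (4+2)/2
    assert profile.frame.at["f2", "Scytonema"] == pytest.approx(1.0)
    assert profile.dominant["f2"] == "Lyngbya" and "f2" not in profile.ties


def test_genus_intensity_single_sample_feature(sim_config):
    spectra, quant, truth = simulate_spectra(sim_config)
    mcfg = sim_config.spectra
    mapping = {s: mcfg.genus_labels[i % len(mcfg.genus_labels)]
               for i, s in enumerate(quant.columns)}
    net = build_network(spectra)
    profile = genus_intensity(net, mapping)
    planted = dict(zip(truth.feature_id, truth.genus))
    for fid, genus in profile.dominant.items():
        assert genus == planted[fid]


def test_genus_intensity_rejects_unmapped_samples():
    net = _network_with_intensities()
    with pytest.raises(ValueError, match="s3"):
        genus_intensity(net, {"s1": "A", "s2": "A"})


def test_graphml_round_trip_and_attributes(tmp_path):
    import networkx as nx

    net = _network_with_intensities()
    profile = genus_intensity(net, {"s1": "A", "s2": "A", "s3": "B"})
    hits = [  # annotate f1 only
        h for h in library_search(
            list(net.spectra.values()),
            [("compound_x", net.spectra["f1"])],
        )
    ]
    path = tmp_path / "net.graphml"
    export_graphml(net, path, profile=profile, hits=hits)
    g = nx.read_graphml(path)
    assert set(g.nodes) == {"f1", "f2"}
    assert g.number_of_edges() == len(net.edges)
    assert g.nodes["f1"]["precursor_mz"] == pytest.approx(500.0)
    assert g.nodes["f1"]["annotation_name"] == "compound_x"
    assert g.nodes["f1"]["dominant_genus"] in ("A", "B")


def test_graphml_empty_network_is_valid(tmp_path, rng):
    import networkx as nx

    spectra = [random_spectrum(rng, 5, f"s{i}", precursor_mz=300.0 + 100 * i)
               for i in range(3)]
    net = build_network(spectra)
    path = tmp_path / "empty.graphml"
    export_graphml(net, path)
    g = nx.read_graphml(path)
    assert g.number_of_edges() == 0 and g.number_of_nodes() == 3
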