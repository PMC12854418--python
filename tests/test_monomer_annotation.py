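import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import moving_average_reference, segment_reference
from ppimodes import (PipelineConfig, annotate_monomer, compute_isd,
                      compute_rsa, map_ss8_to_ss3, segment_true_runs)
from ppimodes.monomer_annotation import (MAX_ACC, residue_sasa,
                                         shrake_rupley_sasa)
from ppimodes.structure_io import AtomRecord, MonomerModel, ResidueView


def _peptide(n: int, spacing: float = 3.8) -> MonomerModel:
    residues = []
    for i in range(1, n + 1):
        atoms = [AtomRecord("A", i, "ALA", name, el,
                            np.array([spacing * i + dx, dy, dz]))
                 for name, el, (dx, dy, dz) in [
                     ("N", "N", (-1.2, 0.4, 0.0)),
                     ("CA", "C", (0.0, 0.0, 0.0)),
                     ("C", "C", (1.2, 0.4, 0.0)),
                     ("O", "O", (1.4, 1.6, 0.0)),
                     ("CB", "C", (0.0, -1.0, 1.2))]]
        residues.append(ResidueView("A", i, "A", atoms, 80.0))
    return MonomerModel(chain=residues)


class TestRsa:
    def test_buried_limit(self):
        m = _peptide(3)
        m.accessibility = np.zeros(3)
        assert compute_rsa(m).tolist() == [0.0, 0.0, 0.0]

    def test_clipping_at_scale_maximum(self):
        m = _peptide(3)
        m.accessibility = np.array([500.0, 50.0, 129.0])
        rsa = compute_rsa(m)
        assert rsa[0] == 1.0
        assert rsa[1] == pytest.approx(50.0 / MAX_ACC["A"])

    def test_unknown_residue_type_rejected(self):
        m = _peptide(2)
        m.accessibility = np.zeros(2)
        with pytest.raises(KeyError):
            compute_rsa(m, max_acc_scale={"G": 104.0})

    def test_sasa_fallback_used_when_accessibility_absent(self):
        m = _peptide(4)
        rsa = compute_rsa(m)
        assert np.all((0 < rsa) & (rsa <= 1.0))

    def test_shrake_rupley_against_biotite(self):
        """Internal SASA matches an independent implementation on the
        same radii, within sphere-sampling resolution."""
        biotite_struct = pytest.importorskip("biotite.structure")
        m = _peptide(6)
        coords, elements = [], []
        for res in m.chain:
            for a in res.heavy_atoms:
                coords.append(a.position)
                elements.append(a.element)
        coords = np.array(coords)
        mine = shrake_rupley_sasa(coords, elements, n_points=2000)

        from ppimodes.monomer_annotation import _PROBE, _VDW
        arr = biotite_struct.AtomArray(len(coords))
        arr.coord = coords
        arr.element = np.array(elements)
        arr.res_id = np.arange(len(coords))
        arr.chain_id = np.array(["A"] * len(coords))
        radii = np.array([_VDW[e] for e in elements])
        ref = biotite_struct.sasa(arr, probe_radius=_PROBE, point_number=2000,
                                  vdw_radii=radii)
        np.testing.assert_allclose(mine, ref, rtol=0.02, atol=0.5)

    def test_residue_sasa_single_atom_closed_form(self):
        # an isolated sphere's SASA is exactly 4*pi*(r + probe)^2
        sasa = shrake_rupley_sasa(np.zeros((1, 3)), ["C"], n_points=500)
        assert sasa[0] == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2)


class TestIsd:
    def test_constant_profile_is_invariant(self):
        isd = compute_isd(np.full(40, 50.0), np.full(40, 0.8), window=25)
        np.testing.assert_allclose(isd.isd, 0.8)

    def test_window_one_is_identity(self):
        rsa = np.linspace(0, 1, 30)
        isd = compute_isd(np.zeros(30), rsa, window=1)
        np.testing.assert_array_equal(isd.isd, rsa)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(7)
        rsa = rng.uniform(0, 1, 83)
        for window in (5, 25):
            isd = compute_isd(np.zeros(83), rsa, window=window)
            np.testing.assert_allclose(
                isd.isd, moving_average_reference(rsa, window), atol=1e-12)

    def test_plddt_variant(self):
        plddt = np.full(30, 40.0)
        isd = compute_isd(plddt, None, window=5, variant="plddt_window")
        np.testing.assert_allclose(isd.isd, 0.6)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            compute_isd(np.zeros(10), np.zeros(10), window=4)


@pytest.mark.parametrize("code8, expected", [
    ("H", "H"), ("G", "H"), ("I", "H"),
    ("E", "E"), ("B", "E"),
    ("T", "C"), ("S", "C"), ("P", "C"), (" ", "C"), ("-", "C"),
])
def test_ss8_to_ss3_mapping(code8, expected):
    assert map_ss8_to_ss3(code8) == expected


class TestSegmentation:
    def test_short_gap_bridged(self):
        mask = np.zeros(30, dtype=bool)
        mask[9:15] = True   # residues 10-15
        mask[17:25] = True  # residues 18-25 (gap 16-17, length 2)
        regions = segment_true_runs(mask, min_len=5, max_gap=2)
        assert [(r.start, r.end) for r in regions] == [(10, 25)]

    def test_all_false_is_empty(self):
        assert segment_true_runs(np.zeros(20, dtype=bool)) == []

    def test_bridge_before_length_filter(self):
        # two 3-runs joined by a 2-gap pass min_len=5 only if bridging
        # happens first
        mask = np.array([1, 1, 1, 0, 0, 1, 1, 1], dtype=bool)
        regions = segment_true_runs(mask, min_len=5, max_gap=2)
        assert [(r.start, r.end) for r in regions] == [(1, 8)]

    def test_matches_reference_on_random_masks(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            n = int(rng.integers(1, 101))
            mask = rng.random(n) < rng.uniform(0.2, 0.8)
            got = [(r.start, r.end)
                   for r in segment_true_runs(mask, min_len=5, max_gap=2)]
            assert got == segment_reference(mask, 5, 2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(mask=st.lists(st.booleans(), min_size=1, max_size=60),
           min_len=st.integers(1, 6), max_gap=st.integers(0, 3))
    def test_property_matches_reference(self, mask, min_len, max_gap):
        got = [(r.start, r.end)
               for r in segment_true_runs(mask, min_len, max_gap)]
        assert got == segment_reference(mask, min_len, max_gap)


class TestAnnotateMonomer:
    @staticmethod
    def _annotate(isd_design, plddt, ss8=None):
        n = len(isd_design)
        ss8 = ss8 or "H" * n
        # encode the designed ISD as RSA and disable smoothing so the
        # designed profile is exactly what segmentation sees
        cfg = PipelineConfig(isd_window=1)
        return annotate_monomer(None, ss8, cfg, plddt=np.asarray(plddt),
                                rsa=np.asarray(isd_design))

    def test_long_idr(self):
        isd = np.where(np.arange(1, 61) <= 35, 0.9, 0.1)
        ann = self._annotate(isd, np.full(60, 50.0))
        assert [(r.start, r.end, r.kind) for r in ann.idr_regions] == \
            [(1, 35, "idr_long")]

    def test_short_idr_under_30(self):
        isd = np.where(np.arange(1, 61) <= 29, 0.9, 0.1)
        ann = self._annotate(isd, np.full(60, 50.0))
        assert [(r.start, r.end, r.kind) for r in ann.idr_regions] == \
            [(1, 29, "idr_short")]

    def test_cf_region_needs_high_plddt_and_isd(self):
        isd = np.full(80, 0.1)
        isd[39:60] = 0.6  # residues 40-60
        plddt = np.full(80, 50.0)
        plddt[39:60] = 80.0
        ann = self._annotate(isd, plddt)
        assert [(r.start, r.end) for r in ann.cf_regions] == [(40, 60)]

    def test_complement_property(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 150))
            isd = rng.uniform(0, 1, n)
            ann = self._annotate(isd, rng.uniform(20, 95, n))
            covered = np.zeros(n, dtype=int)
            for r in ann.idr_regions + ann.ordered_regions:
                covered[r.start - 1:r.end] += 1
            assert (covered == 1).all()

    def test_idr_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        n = 120
        isd = rng.uniform(0, 1, n)
        plddt = rng.uniform(20, 95, n)
        totals = []
        for thr in (0.3, 0.5, 0.7):
            cfg = PipelineConfig(isd_window=1, isd_threshold=thr)
            ann = annotate_monomer(None, "H" * n, cfg, plddt=plddt, rsa=isd)
            totals.append(sum(len(r) for r in ann.idr_regions))
        assert totals == sorted(totals, reverse=True)

    def test_cf_subset_of_high_isd(self):
        rng = np.random.default_rng(9)
        n = 150
        isd = rng.uniform(0, 1, n)
        plddt = rng.uniform(20, 95, n)
        ann = self._annotate(isd, plddt)
        for r in ann.cf_regions:
            # every CF run was seeded by isd > 0.5 residues (gaps <= 2
            # may be bridged, but the run must contain high-ISD residues)
            assert np.any(isd[r.start - 1:r.end] > 0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            annotate_monomer(None, "HHH", PipelineConfig(),
                             plddt=np.zeros(5), rsa=np.zeros(5))
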