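import numpy as np
import pydicom
import pytest

from autocontour.dicom_io import (
    ContourPolygon,
    DicomIOError,
    contours_to_mask,
    mask_to_contours,
    read_ct_series,
    read_rtstruct,
    write_rtstruct,
    StructureSet,
)
from autocontour.metrics import dsc

from _oracles import rasterize_polygon
from conftest import make_volume


# ---------------------------------------------------------------------------
# CT series reading


class TestReadCTSeries:
    def test_hu_conversion_and_geometry(self, small_phantom, small_phantom_dir):
        volume, _ = small_phantom
        reread = read_ct_series(small_phantom_dir)
        assert np.abs(reread.voxels - volume.voxels).max() <= 0.5
        assert reread.pixel_spacing == pytest.approx(volume.pixel_spacing)
        assert reread.slice_thickness == pytest.approx(2.5)
        assert reread.voxels.shape == volume.voxels.shape

    def test_slices_sorted_regardless_of_filename_order(self, small_phantom_dir, tmp_path):
        # copy with adversarial names: reverse slice order lexically
        files = sorted(small_phantom_dir.glob("CT_*.dcm"))
        for i, f in enumerate(files):
            (tmp_path / f"zz_{len(files) - i:03d}.dcm").write_bytes(f.read_bytes())
        a = read_ct_series(small_phantom_dir)
        b = read_ct_series(tmp_path)
        assert np.array_equal(a.slice_positions, b.slice_positions)
        assert np.array_equal(a.voxels, b.voxels)
        assert np.all(np.diff(b.slice_positions) > 0)

    def test_mixed_series_rejected(self, small_phantom_dir, tmp_path):
        for f in sorted(small_phantom_dir.glob("CT_*.dcm"))[:3]:
            (tmp_path / f.name).write_bytes(f.read_bytes())
        ds = pydicom.dcmread(tmp_path / "CT_000.dcm")
        ds.SeriesInstanceUID = "1.2.3.999"
        ds.save_as(tmp_path / "CT_000.dcm", enforce_file_format=True)
        with pytest.raises(DicomIOError, match="mixed series"):
            read_ct_series(tmp_path)

    def test_nonuniform_gap_rejected(self, small_phantom_dir, tmp_path):
        for f in sorted(small_phantom_dir.glob("CT_*.dcm"))[:4]:
            (tmp_path / f.name).write_bytes(f.read_bytes())
        ds = pydicom.dcmread(tmp_path / "CT_003.dcm")
        pos = ds.ImagePositionPatient
        ds.ImagePositionPatient = [pos[0], pos[1], float(pos[2]) + 1.3]
        ds.save_as(tmp_path / "CT_003.dcm", enforce_file_format=True)
        with pytest.raises(DicomIOError, match="non-uniform"):
            read_ct_series(tmp_path)

    def test_missing_rescale_rejected(self, small_phantom_dir, tmp_path):
        for f in sorted(small_phantom_dir.glob("CT_*.dcm"))[:3]:
            (tmp_path / f.name).write_bytes(f.read_bytes())
        ds = pydicom.dcmread(tmp_path / "CT_001.dcm")
        del ds.RescaleSlope
        ds.save_as(tmp_path / "CT_001.dcm", enforce_file_format=True)
        with pytest.raises(DicomIOError, match="rescale"):
            read_ct_series(tmp_path)

    def test_too_few_files_rejected(self, tmp_path):
        with pytest.raises(DicomIOError, match=">= 2"):
            read_ct_series(tmp_path)


# ---------------------------------------------------------------------------
# Rasterization


class TestContoursToMask:
    def test_empty_list_gives_empty_mask(self, volume_64):
        assert not contours_to_mask([], volume_64).any()

    def test_square_area_exact(self, volume_64):
        # pixel centers at integer mm; a [-0.5, 9.5] square covers 10x10 centers
        sq = np.array([
            [-0.5, -0.5, 0.0], [9.5, -0.5, 0.0], [9.5, 9.5, 0.0], [-0.5, 9.5, 0.0],
        ])
        mask = contours_to_mask([ContourPolygon(0, sq)], volume_64)
        assert mask[0].sum() == 100
        assert mask[1:].sum() == 0

    def test_disjoint_squares_union_additive(self, volume_64):
        z = float(volume_64.slice_positions[2])
        sq1 = np.array([[0.5, 0.5, z], [10.5, 0.5, z], [10.5, 10.5, z], [0.5, 10.5, z]])
        sq2 = sq1 + np.array([30.0, 30.0, 0.0])
        mask = contours_to_mask(
            [ContourPolygon(2, sq1), ContourPolygon(2, sq2)], volume_64
        )
        from _oracles import flood_components
        comps = flood_components(mask)
        assert len(comps) == 2
        assert mask.sum() == 2 * 100

    def test_bad_polygons_rejected(self, volume_64):
        with pytest.raises(ValueError):
            ContourPolygon(0, np.array([[0, 0, 0], [1, 1, 0]]))
        poly = ContourPolygon(0, np.array([[0, 0, 99.0], [5, 0, 99.0], [5, 5, 99.0]]))
        with pytest.raises(DicomIOError, match="no slice"):
            contours_to_mask([poly], volume_64)

    def test_matches_bruteforce_on_random_convex_polygons(self):
        # exact agreement with a per-point even-odd oracle
        rng = np.random.default_rng(42)
        vol = make_volume(shape=(1, 48, 48))
        for _ in range(100):
            n = rng.integers(3, 9)
            angles = np.sort(rng.uniform(0, 2 * np.pi, n))
            radii = rng.uniform(4, 18)
            cx, cy = rng.uniform(14, 34, 2)
            xy = np.column_stack([
                cx + radii * np.cos(angles), cy + radii * np.sin(angles)
            ])
            poly = ContourPolygon(0, np.column_stack([xy, np.zeros(n)]))
            mask = contours_to_mask([poly], vol)
            expected = rasterize_polygon(xy, (48, 48))
            assert np.array_equal(mask[0], expected)


class TestMaskToContours:
    def test_empty_mask_empty_list(self, volume_64):
        assert mask_to_contours(np.zeros(volume_64.shape, bool), volume_64) == []

    def test_square_area_via_shoelace(self, volume_64):
        mask = np.zeros(volume_64.shape, bool)
        mask[0, 10:20, 10:20] = True
        polys = mask_to_contours(mask, volume_64)
        assert len(polys) == 1
        pts = polys[0].points[:, :2]
        x, y = pts[:, 0], pts[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
        assert area == pytest.approx(100.0, rel=0.10)

    def test_two_blobs_two_polygons(self, volume_64):
        mask = np.zeros(volume_64.shape, bool)
        mask[1, 5:12, 5:12] = True
        mask[1, 30:40, 30:40] = True
        assert len(mask_to_contours(mask, volume_64)) == 2


# ---------------------------------------------------------------------------
# RTSTRUCT round trips


class TestRTStruct:
    def test_metadata_round_trip(self, volume_64, tmp_path):
        structs = StructureSet(ct_ref=volume_64.series_uid)
        for i, name in enumerate(["brainstem", "parotid_l", "larynx"]):
            mask = np.zeros(volume_64.shape, bool)
            mask[i, 10 + i:25 + i, 10:25] = True
            structs.add(name, mask, number=i + 1)
        path = write_rtstruct(structs, volume_64, tmp_path / "rs.dcm")
        reread = read_rtstruct(path, volume_64)
        assert reread.names() == ["brainstem", "parotid_l", "larynx"]
        assert [r.number for r in reread.rois.values()] == [1, 2, 3]

    def test_box_round_trip_dsc(self, tmp_path):
        vol = make_volume(shape=(5, 40, 40))
        mask = np.zeros(vol.shape, bool)
        mask[:, 10:30, 10:30] = True  # 20x20 on every slice
        structs = StructureSet(ct_ref=vol.series_uid)
        structs.add("box", mask)
        path = write_rtstruct(structs, vol, tmp_path / "rs.dcm")
        reread = read_rtstruct(path, vol)
        assert dsc(mask, reread.rois["box"].mask) >= 0.99

    def test_sphere_volume_close_to_analytic(self, tmp_path):
        vol = make_volume(shape=(22, 64, 64), thickness=1.0)
        zz, yy, xx = np.mgrid[0:22, 0:64, 0:64].astype(float)
        r = 9.0
        mask = ((zz - 11) ** 2 + (yy - 32) ** 2 + (xx - 32) ** 2) <= r ** 2
        structs = StructureSet(ct_ref=vol.series_uid)
        structs.add("sphere", mask)
        path = write_rtstruct(structs, vol, tmp_path / "rs.dcm")
        reread = read_rtstruct(path, vol)
        analytic = 4.0 / 3.0 * np.pi * r ** 3
        assert reread.rois["sphere"].mask.sum() == pytest.approx(analytic, rel=0.05)

    def test_frame_of_reference_mismatch_rejected(self, volume_64, tmp_path):
        structs = StructureSet(ct_ref=volume_64.series_uid)
        mask = np.zeros(volume_64.shape, bool)
        mask[0, 5:15, 5:15] = True
        structs.add("roi", mask)
        path = write_rtstruct(structs, volume_64, tmp_path / "rs.dcm")
        other = make_volume()
        other.frame_of_reference_uid = "9.9.9"
        with pytest.raises(DicomIOError, match="frame"):
            read_rtstruct(path, other)

    def test_single_pixel_roi_still_emitted(self, volume_64, tmp_path):
        structs = StructureSet(ct_ref=volume_64.series_uid)
        mask = np.zeros(volume_64.shape, bool)
        mask[2, 20, 20] = True
        structs.add("dot", mask)
        path = write_rtstruct(structs, volume_64, tmp_path / "rs.dcm")
        reread = read_rtstruct(path, volume_64)
        assert "dot" in reread.names()  # round-trip DSC exempt at this size

    def test_empty_structure_set_warns_but_writes(self, volume_64, tmp_path):
        structs = StructureSet(ct_ref=volume_64.series_uid)
        with pytest.warns(UserWarning, match="zero ROIs"):
            path = write_rtstruct(structs, volume_64, tmp_path / "rs.dcm")
        ds = pydicom.dcmread(path)
        assert len(ds.StructureSetROISequence) == 0

    def test_random_blob_round_trips(self, tmp_path):
        from _oracles import random_blob_mask

        rng = np.random.default_rng(3)
        vol = make_volume(shape=(6, 64, 64))
        for i in range(10):
            mask = random_blob_mask(rng, vol.shape)
            structs = StructureSet(ct_ref=vol.series_uid)
            structs.add("blob", mask)
            path = write_rtstruct(structs, vol, tmp_path / f"rs{i}.dcm")
            reread = read_rtstruct(path, vol)
            assert dsc(mask, reread.rois["blob"].mask) >= 0.99

    def test_contours_reference_ct_sop_instances(self, small_phantom, tmp_path):
        volume, structs = small_phantom
        path = write_rtstruct(structs, volume, tmp_path / "rs.dcm")
        ds = pydicom.dcmread(path)
        uids = set(volume.sop_instance_uids)
        for rc in ds.ROIContourSequence:
            for c in rc.ContourSequence:
                ref = c.ContourImageSequence[0].ReferencedSOPInstanceUID
                assert ref in uids
                # contour z matches the referenced slice's position
                k = volume.sop_instance_uids.index(ref)
                z = np.asarray(c.ContourData[2::3], dtype=float)
                assert np.allclose(z, volume.slice_positions[k], atol=0.01)
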