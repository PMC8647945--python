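"""Channel sensitivity math against brute-force references and invariants."""

import numpy as np
import pytest

from nirsmap.mc import FluenceVolume
from nirsmap.sensitivity import (
    ChannelSensitivityField,
    SpecificityTable,
    brain_sens,
    channel_coordinate,
    channel_norm_sens,
    compute_channel_record,
    separation,
    specificity,
    specificity_from_uncorrected,
    uncorrected_sensitivity,
)
from nirsmap.volumes import AtlasVolume, FourClassVolume

from _reference import (
    ref_brain_sens,
    ref_compartment_sums,
    ref_coordinate,
    ref_norm_sens,
    ref_separation,
    ref_specificity,
)


def _fluence(values, affine=None, normalized=True):
    return FluenceVolume(
        values=np.asarray(values, float), affine=affine or np.eye(4),
        launch_position=np.zeros(3),
        normalization="normalized" if normalized else "raw",
        total_absorbed_weight=1.0)


def _toy_world(rng, shape=(4, 5, 3)):
    """Random fluence pair + segmentation + atlas on a tiny grid."""
    fl_s = rng.random(shape) + 0.01
    fl_d = rng.random(shape) + 0.01
    four = rng.integers(0, 6, size=shape).astype(np.int16)
    roi = np.zeros(shape, np.int16)
    brain = four == 4
    roi[brain] = rng.integers(0, 3, size=int(brain.sum()))
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = (-1.0, 3.0, 0.5)
    return fl_s, fl_d, four, roi, affine


def test_operations_match_nested_loop_reference(rng):
    """All channel operations agree with a plain-loop oracle to 1e-12."""
    for _ in range(3):
        fl_s, fl_d, four, roi, affine = _toy_world(rng)
        if not (four == 4).any():
            continue
        field = channel_norm_sens(_fluence(fl_s, list(affine)),
                                  _fluence(fl_d, list(affine)))
        ref_field = ref_norm_sens(fl_s, fl_d)
        assert np.allclose(field.values, ref_field, rtol=1e-12, atol=0)

        four_vol = FourClassVolume(labels=four, affine=affine)
        atlas = AtlasVolume(labels=roi, affine=affine,
                            roi_names={1: "A", 2: "B"})
        bs = brain_sens(field, four_vol)
        assert bs == pytest.approx(ref_brain_sens(ref_field, four), rel=1e-12)
        if bs <= 0:
            continue
        spec = specificity(field, atlas, four_vol)
        ref = ref_specificity(ref_field, roi, four, [1, 2])
        assert spec["A"] == pytest.approx(ref[1], rel=1e-12)
        assert spec["B"] == pytest.approx(ref[2], rel=1e-12)
        assert spec["Brain_Outside"] == pytest.approx(ref["Brain_Outside"],
                                                      rel=1e-12)
        unc = uncorrected_sensitivity(field, atlas, four_vol)
        by_label = ref_compartment_sums(ref_field, four)
        assert unc["scalp"] == pytest.approx(by_label.get(1, 0.0), rel=1e-12)
        assert unc["skull"] == pytest.approx(by_label.get(2, 0.0), rel=1e-12)
        assert unc["CSF"] == pytest.approx(by_label.get(3, 0.0), rel=1e-12)
        assert unc["other"] == pytest.approx(by_label.get(5, 0.0), rel=1e-12)
        coord = channel_coordinate(field, four_vol)
        assert np.allclose(coord, ref_coordinate(ref_field, four, affine),
                           rtol=1e-12)


def test_norm_sens_is_symmetric_and_scale_invariant(rng):
    fl_s, fl_d, *_ = _toy_world(rng)
    a = channel_norm_sens(_fluence(fl_s), _fluence(fl_d))
    b = channel_norm_sens(_fluence(fl_d), _fluence(fl_s))
    assert np.array_equal(a.values, b.values)
    scaled = channel_norm_sens(_fluence(fl_s * 7.3), _fluence(fl_d * 0.02))
    assert np.allclose(a.values, scaled.values, rtol=1e-12)
    assert a.values.sum() == pytest.approx(1.0, abs=1e-12)


def test_norm_sens_single_shared_voxel():
    fl_s = np.zeros((3, 3, 3))
    fl_d = np.zeros((3, 3, 3))
    fl_s[1, 1, 1] = 0.4
    fl_d[1, 1, 1] = 0.9
    fl_d[0, 0, 0] = 0.3  # not shared with the source
    field = channel_norm_sens(_fluence(fl_s), _fluence(fl_d))
    assert field.values[1, 1, 1] == 1.0
    assert field.values.sum() == 1.0


def test_norm_sens_error_conditions():
    with pytest.raises(ValueError, match="not normalized"):
        channel_norm_sens(_fluence(np.ones((2, 2, 2)), normalized=False),
                          _fluence(np.ones((2, 2, 2))))
    with pytest.raises(ValueError, match="disconnected"):
        a = np.zeros((2, 2, 2)); a[0, 0, 0] = 1.0
        b = np.zeros((2, 2, 2)); b[1, 1, 1] = 1.0
        channel_norm_sens(_fluence(a), _fluence(b))
    with pytest.raises(ValueError, match="grids differ"):
        channel_norm_sens(_fluence(np.ones((2, 2, 2))),
                          _fluence(np.ones((3, 3, 3))))


def _field(values, affine=None):
    v = np.asarray(values, float)
    return ChannelSensitivityField(values=v / v.sum(),
                                   affine=affine if affine is not None
                                   else np.eye(4))


def test_brain_sens_extremes_and_forced_split():
    four = np.zeros((2, 2, 2), np.int16)
    four[0] = 4  # brain
    four[1] = 1  # scalp
    fv = FourClassVolume(labels=four, affine=np.eye(4))
    inside = np.zeros((2, 2, 2)); inside[0] = 1.0
    assert brain_sens(_field(inside), fv) == pytest.approx(1.0)
    outside = np.zeros((2, 2, 2)); outside[1] = 1.0
    assert brain_sens(_field(outside), fv) == pytest.approx(0.0)
    split = np.zeros((2, 2, 2))
    split[0, 0, 0] = 0.3
    split[1, 0, 0] = 0.7
    assert brain_sens(_field(split), fv) == pytest.approx(0.3)


def test_specificity_hand_computed_four_voxel_brain():
    # 4 brain voxels with field (0.1, 0.2, 0.3, 0.1); ROI A = first two
    four = np.full((4, 1, 1), 4, np.int16)
    roi = np.array([1, 1, 0, 0], np.int16).reshape(4, 1, 1)
    vals = np.array([0.1, 0.2, 0.3, 0.1]).reshape(4, 1, 1)
    vals = np.concatenate([vals, np.full((4, 1, 1), 0.075)], axis=1)
    four = np.concatenate([four, np.ones((4, 1, 1), np.int16)], axis=1)
    roi = np.concatenate([roi, np.zeros((4, 1, 1), np.int16)], axis=1)
    field = ChannelSensitivityField(values=vals, affine=np.eye(4))
    fv = FourClassVolume(labels=four, affine=np.eye(4))
    atlas = AtlasVolume(labels=roi, affine=np.eye(4), roi_names={1: "A"})
    spec = specificity(field, atlas, fv)
    assert spec["A"] == pytest.approx(100 * 0.3 / 0.7, rel=1e-12)
    assert spec["Brain_Outside"] == pytest.approx(100 * 0.4 / 0.7, rel=1e-12)
    assert sum(spec.values()) == pytest.approx(100.0, abs=1e-9)


def test_specificity_single_roi_covering_brain():
    four = np.full((3, 3, 3), 4, np.int16)
    roi = np.ones((3, 3, 3), np.int16)
    field = _field(np.random.default_rng(1).random((3, 3, 3)))
    spec = specificity(field, AtlasVolume(labels=roi, affine=np.eye(4),
                                          roi_names={1: "All"}),
                       FourClassVolume(labels=four, affine=np.eye(4)))
    assert spec["All"] == pytest.approx(100.0)
    assert spec["Brain_Outside"] == pytest.approx(0.0)


def test_specificity_even_split_between_two_rois():
    four = np.full((2, 1, 1), 4, np.int16)
    roi = np.array([1, 2], np.int16).reshape(2, 1, 1)
    field = _field(np.array([0.5, 0.5]).reshape(2, 1, 1))
    spec = specificity(field, AtlasVolume(labels=roi, affine=np.eye(4),
                                          roi_names={1: "L", 2: "R"}),
                       FourClassVolume(labels=four, affine=np.eye(4)))
    assert spec["L"] == pytest.approx(50.0)
    assert spec["R"] == pytest.approx(50.0)


def test_specificity_blind_channel_rejected():
    four = np.ones((2, 2, 2), np.int16)  # scalp only
    field = _field(np.ones((2, 2, 2)))
    atlas = AtlasVolume(labels=np.zeros((2, 2, 2), np.int16),
                        affine=np.eye(4), roi_names={})
    with pytest.raises(ValueError, match="zero brain"):
        specificity(field, atlas, FourClassVolume(labels=four,
                                                  affine=np.eye(4)))


def test_uncorrected_all_mass_in_skull_and_identity():
    four = np.full((2, 2, 2), 2, np.int16)  # skull
    field = _field(np.ones((2, 2, 2)))
    atlas = AtlasVolume(labels=np.zeros((2, 2, 2), np.int16),
                        affine=np.eye(4), roi_names={1: "A"})
    unc = uncorrected_sensitivity(field, atlas,
                                  FourClassVolume(labels=four,
                                                  affine=np.eye(4)))
    assert unc["skull"] == pytest.approx(1.0)
    assert sum(v for k, v in unc.items() if k != "skull") == 0.0


def test_specificity_recomputed_from_uncorrected_is_identical(rng):
    fl_s, fl_d, four, roi, affine = _toy_world(rng, shape=(5, 5, 5))
    four[0, 0, 0] = 4  # guarantee brain mass
    field = channel_norm_sens(_fluence(fl_s, list(affine)),
                              _fluence(fl_d, list(affine)))
    fv = FourClassVolume(labels=four, affine=affine)
    atlas = AtlasVolume(labels=roi, affine=affine, roi_names={1: "A", 2: "B"})
    direct = specificity(field, atlas, fv)
    via_unc = specificity_from_uncorrected(
        uncorrected_sensitivity(field, atlas, fv))
    for k, v in direct.items():
        assert via_unc[k] == pytest.approx(v, rel=1e-12)


def test_coordinate_point_mass_and_interpolation():
    four = np.full((2, 1, 1), 4, np.int16)
    affine = np.diag([10.0, 1.0, 1.0, 1.0])
    fv = FourClassVolume(labels=four, affine=affine)
    point = _field(np.array([1.0, 0.0]).reshape(2, 1, 1), affine)
    assert np.allclose(channel_coordinate(point, fv), [0, 0, 0])
    mixed = _field(np.array([0.25, 0.75]).reshape(2, 1, 1), affine)
    assert np.allclose(channel_coordinate(mixed, fv), [7.5, 0, 0])


def test_coordinate_of_symmetric_field_is_on_midline():
    four = np.full((4, 3, 3), 4, np.int16)
    affine = np.eye(4)
    affine[:3, 3] = (-1.5, 0, 0)  # x symmetric about 0
    vals = np.random.default_rng(3).random((4, 3, 3))
    vals = vals + vals[::-1]
    field = _field(vals, affine)
    coord = channel_coordinate(field, FourClassVolume(labels=four,
                                                      affine=affine))
    assert abs(coord[0]) < 1e-9


def test_separation_basics_and_montage_chords(sphere_montage, montage_tables):
    assert separation([1, 2, 3], [1, 2, 3]) == 0.0
    assert separation([0, 0, 0], [3, 4, 0]) == pytest.approx(5.0)
    _, _, electrodes = sphere_montage
    _, channels = montage_tables
    from _reference import sphere_10_10
    from conftest import SPHERE_RADIUS
    oracle = sphere_10_10(SPHERE_RADIUS)
    for s, d in channels:
        got = separation(electrodes[s], electrodes[d])
        expect = ref_separation(oracle[s], oracle[d])
        assert abs(got - expect) < 2.5, (s, d)


def test_record_and_table_row_sums_on_simulated_channel(
        ellipsoid_phantom, ellipsoid_electrodes, fluence_pair):
    """A real Monte Carlo channel satisfies the normalization contracts."""
    _, tissue, four, atlas = ellipsoid_phantom
    field = channel_norm_sens(fluence_pair["Fpz"], fluence_pair["AFz"],
                              channel_id="Fpz-AFz", source="Fpz",
                              detector="AFz")
    rec = compute_channel_record(field, atlas, four,
                                 ellipsoid_electrodes["Fpz"],
                                 ellipsoid_electrodes["AFz"])
    assert sum(rec.specificity.values()) == pytest.approx(100.0, abs=1e-6)
    assert sum(rec.uncorrected.values()) == pytest.approx(1.0, abs=1e-6)
    assert rec.brain_sens == pytest.approx(
        sum(v for k, v in rec.uncorrected.items()
            if k not in ("scalp", "skull", "CSF", "other")), abs=1e-12)
    assert 0.0 < rec.brain_sens < 1.0
    # the sensitivity-weighted coordinate lies inside the brain bounding box
    brain_world = four.voxel_to_world(np.argwhere(four.brain_mask()))
    assert (rec.coordinate >= brain_world.min(axis=0) - 1e-9).all()
    assert (rec.coordinate <= brain_world.max(axis=0) + 1e-9).all()
    table = SpecificityTable.from_records([rec])
    assert table.row_sums().iloc[0] == pytest.approx(100.0, abs=1e-6)
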