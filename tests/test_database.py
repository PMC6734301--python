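"""Slab database: build, persistence, slab choice and macro-step sampling."""

import numpy as np
import pytest
from scipy import stats

from pmmc import hu_to_mix, csda_range
from pmmc.database import (SlabDatabase, build_database, choose_slab,
                           sample_macro_step, pack_tables,
                           AVAILABILITY_RANGE_FRACTION)


def test_build_completeness(small_db, ramp):
    # every (material, energy) pair has at least the smallest slab recorded
    for mat in ramp.nodes:
        for e in small_db.energy_grid:
            assert (mat.name, float(e), float(small_db.slab_sizes[0])) \
                in small_db.records
    # and every record honors the availability rule or is the forced smallest
    for (name, e, t), rec in small_db.records.items():
        mat = ramp.nodes[ramp.material_index(name)]
        limit = AVAILABILITY_RANGE_FRACTION * csda_range(mat, e)
        assert t <= limit or t == float(small_db.slab_sizes[0])
        rec.validate()


def test_availability_muscle_at_10mev(small_db, ramp):
    # range(muscle, 10) ~ 0.116 cm -> only the 0.05 cm slab is available
    mix = hu_to_mix(ramp, 40)
    avail = small_db.available_slabs(mix, 10.0)
    assert list(avail) == [0.05]


def test_database_roundtrip(tmp_path, small_db):
    path = tmp_path / "db.h5"
    small_db.save(path)
    back = SlabDatabase.load(path, config=small_db.config)
    assert set(back.records) == set(small_db.records)
    for key, rec in small_db.records.items():
        other = back.records[key]
        assert np.array_equal(rec.h_energy_loss, other.h_energy_loss)
        assert np.array_equal(rec.h_exit, other.h_exit)
        assert np.array_equal(rec.de_edges, other.de_edges)
        assert rec.p_elastic == other.p_elastic
    assert np.array_equal(back.energy_grid, small_db.energy_grid)


def test_build_deterministic(tmp_path, ramp):
    kw = dict(energy_grid=(10.0, 20.0), slab_sizes=(0.05, 0.1),
              n_per_record=1000, seed=3)
    a = build_database(ramp, **kw)
    b = build_database(ramp, **kw)
    pa, pb = tmp_path / "a.h5", tmp_path / "b.h5"
    a.save(pa)
    b.save(pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_config_hash_mismatch_warns(tmp_path, small_db):
    from pmmc.presim import CondensedStepConfig
    path = tmp_path / "db.h5"
    small_db.save(path)
    with pytest.warns(UserWarning, match="different physics config"):
        SlabDatabase.load(path, config=CondensedStepConfig(micro_step=0.004))


def test_choose_slab_nearest_and_ties(small_db, ramp):
    mix = hu_to_mix(ramp, 40)
    # at 40 MeV (range ~ 1.6 cm) slabs up to 0.5 cm are available
    assert choose_slab(small_db, mix, 40.0, d=0.7, lateral_distance=1.0,
                       lateral_threshold=0.05) == 0.5
    # tie between 0.1 and 0.2 at d = 0.15 breaks toward the smaller slab
    assert choose_slab(small_db, mix, 40.0, d=0.15, lateral_distance=1.0,
                       lateral_threshold=0.05) == 0.1
    # below the lateral threshold the smallest available slab is forced
    assert choose_slab(small_db, mix, 40.0, d=0.7, lateral_distance=0.04,
                       lateral_threshold=0.05) == 0.05
    with pytest.raises(ValueError):
        choose_slab(small_db, mix, 40.0, d=0.0, lateral_distance=1.0,
                    lateral_threshold=0.05)


def test_sample_macro_step_chi_square_fidelity(small_db, ramp):
    # a pure node material (weight 0) must reproduce the source dE histogram
    mix = hu_to_mix(ramp, 40)  # muscle node exactly: weight 0 in its band
    assert mix.weight == 0.0
    rng = np.random.default_rng(5)
    eg = 30.0
    slab = 0.2
    rec = small_db.record("muscle", eg, slab)
    n = 100_000
    des = np.array([
        sample_macro_step(small_db, mix, eg, slab, (0, 0, 0), (0, 0, 1), rng
                          ).delta_e
        for _ in range(n)])
    counts, _ = np.histogram(des, bins=rec.de_edges)
    expected = rec.h_energy_loss * n
    m = expected > 10
    chi2 = float(((counts[m] - expected[m]) ** 2 / expected[m]).sum())
    p = stats.chi2.sf(chi2, df=int(m.sum()) - 1)
    assert p > 0.01


def test_sample_macro_step_contracts(small_db, ramp):
    mix = hu_to_mix(ramp, 40)
    rng = np.random.default_rng(6)
    for _ in range(500):
        s = sample_macro_step(small_db, mix, 30.0, 0.2, (1, 2, 3), (0, 0, 1),
                              rng)
        assert 0.0 <= s.delta_e <= 30.0
        assert np.linalg.norm(s.exit_direction) == pytest.approx(1.0, abs=1e-9)
        lateral = np.asarray(s.exit_position) - np.array([1, 2, 3.2])
        assert np.linalg.norm(lateral[:2]) <= 0.2  # displacement <= slab
        if s.process != "none":
            seg = np.asarray(s.process_point) - np.array([1, 2, 3])
            assert 0.0 <= seg[2] <= 0.2 + 1e-12


def test_pack_tables_shapes(small_db, ramp):
    tb = pack_tables(small_db)
    M, NE, NT = len(ramp.nodes), small_db.energy_grid.size, \
        small_db.slab_sizes.size
    assert tb.avail.shape == (M, NE, NT)
    assert tb.de_cdf.shape[:3] == (M, NE, NT)
    # every CDF of an available record ends at 1
    for m in range(M):
        for ei in range(NE):
            for ti in range(NT):
                if tb.avail[m, ei, ti]:
                    assert tb.de_cdf[m, ei, ti, -1] == pytest.approx(1.0)
                    assert tb.ex_cdf[m, ei, ti, -1] == pytest.approx(1.0)
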