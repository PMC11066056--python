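"""Image cytometry: segmentation, gating partition, FDC, pooling."""

import numpy as np
import pytest

import zombiescope as z
from zombiescope.cytometry import (CellObject, GateConfig, estimate_threshold,
                                   tabulate)
from zombiescope.synthetic_imaging import FieldImage


def _flood_fill_count(mask, connectivity):
    """Brute-force BFS component count, independent of skimage."""
    if connectivity == 2:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    h, w = mask.shape
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                count += 1
                stack = [(i, j)]
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
    return count


def _mk_field(dna=None, rrna=None, phage=None, shape=None,
              pixel_size=0.05, bg=0.0):
    for plane in (dna, rrna, phage):
        if plane is not None:
            shape = plane.shape
            break
    base = np.full(shape or (32, 32), bg, dtype=float)
    return FieldImage(
        dna=dna if dna is not None else base.copy(),
        rrna=rrna if rrna is not None else base.copy(),
        phage=phage if phage is not None else base.copy(),
        pixel_size=pixel_size,
    )


def test_segment_count_matches_flood_fill_oracle(small_scene, gates):
    spec, field, truth = small_scene
    objs = z.segment_objects(field, gates)
    # oracle: threshold union, count components by BFS
    union = np.zeros(field.shape, dtype=bool)
    for ch in z.CHANNELS:
        union |= field.channel(ch) > estimate_threshold(field.channel(ch),
                                                        gates, ch)
    assert len(objs) == _flood_fill_count(union, gates.connectivity)
    assert len(objs) == len(truth)


def test_uniform_background_yields_no_objects():
    field = _mk_field(bg=20.0)
    assert z.segment_objects(field, GateConfig()) == []
    field0 = _mk_field(bg=0.0)
    assert z.segment_objects(field0, GateConfig()) == []


def test_corner_touching_blobs_connectivity():
    dna = np.zeros((20, 20))
    dna[2:6, 2:6] = 100.0
    dna[6:10, 6:10] = 100.0   # touches corner-to-corner at (5,5)/(6,6)
    field = _mk_field(dna=dna)
    cfg8 = GateConfig(connectivity=2, min_threshold_offset=10)
    cfg4 = GateConfig(connectivity=1, min_threshold_offset=10)
    assert len(z.segment_objects(field, cfg8)) == 1
    assert len(z.segment_objects(field, cfg4)) == 2
    # agrees with the BFS oracle
    assert _flood_fill_count(dna > 10, 2) == 1
    assert _flood_fill_count(dna > 10, 1) == 2


def _obj(dna, rrna, phage, area):
    return CellObject(
        id=1, mask=np.ones((2, 2), bool), bbox=(0, 0, 2, 2), area=area,
        equivalent_diameter=float(np.sqrt(4 * area / np.pi)),
        centroid=(1.0, 1.0),
        mean_intensity={"dna": 0, "rrna": 0, "phage": 0},
        max_intensity={"dna": 0, "rrna": 0, "phage": 0},
        positive={"dna": dna, "rrna": rrna, "phage": phage},
    )


GATE = GateConfig(free_phage_max_area=0.05, min_cell_area=0.06)


@pytest.mark.parametrize("dna,rrna,phage,area,expected", [
    (True, True, True, 0.3, "infected_sar11"),
    (True, True, False, 0.3, "sar11"),
    (True, False, True, 0.3, "zombie"),        # DNA+, phage+, large: zombie
    (False, False, True, 0.03, "free_phage_or_vesicle"),
    (True, False, True, 0.03, "free_phage_or_vesicle"),
    (True, False, False, 0.3, "total_only"),
    (False, False, True, 0.3, "rejected"),     # large phage-only, no DNA
    (False, True, False, 0.3, "rejected"),
    (True, False, False, 0.03, "rejected"),    # sub-cellular DNA speck
])
def test_classification_partition(dna, rrna, phage, area, expected):
    """Gating: SAR11 = DNA+rRNA; infected adds phage; zombie = DNA+phage
    without rRNA above the free-phage size gate; small phage objects are
    free phage or vesicles."""
    assert z.classify_object(_obj(dna, rrna, phage, area), GATE) == expected


def test_every_object_gets_exactly_one_label(noisy_scene):
    spec, field, _ = noisy_scene
    cfg = z.calibrate_gates(spec)
    objs = z.classify_objects(z.segment_objects(field, cfg), cfg)
    assert all(o.label in z.cytometry.LABELS for o in objs)
    res = z.tabulate(objs, cfg)
    accounted = (res.total_cells + res.free_phage_objects
                 + res.rejected_objects)
    assert accounted == len(objs)


def test_dna_maxima_two_foci_vs_one():
    """Two Gaussian foci separated by 4x their sigma give 2 maxima; one
    focus gives 1; a flat plateau merges to 1 (exhaustive neighborhood
    oracle on the crafted profiles)."""
    yy, xx = np.mgrid[0:40, 0:40]

    def gauss(cy, cx, s=2.0, amp=100.0):
        return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))

    cfg = GateConfig(maxima_smooth_sigma_px=0.0, maxima_prominence=5.0)
    mask = np.ones((40, 40), bool)
    obj = CellObject(id=1, mask=mask, bbox=(0, 0, 40, 40), area=4.0,
                     equivalent_diameter=2.0, centroid=(20, 20),
                     mean_intensity={}, max_intensity={},
                     positive={"dna": True, "rrna": False, "phage": False})

    two = gauss(20, 16) + gauss(20, 24)      # separation 8 = 4 x sigma
    assert z.count_dna_maxima(obj, two, cfg) == 2
    # oracle: count strict local maxima by exhaustive 8-neighborhood scan
    n_strict = 0
    for i in range(1, 39):
        for j in range(1, 39):
            patch = two[i - 1:i + 2, j - 1:j + 2]
            if two[i, j] == patch.max() and (patch == two[i, j]).sum() == 1:
                n_strict += 1
    assert n_strict == 2

    one = gauss(20, 20)
    assert z.count_dna_maxima(obj, one, cfg) == 1

    plateau = np.zeros((40, 40))
    plateau[15:25, 15:25] = 50.0
    assert z.count_dna_maxima(obj, plateau, cfg) == 1

    with pytest.raises(ValueError):
        empty = CellObject(id=2, mask=np.zeros((2, 2), bool),
                           bbox=(0, 0, 2, 2), area=0.0,
                           equivalent_diameter=0.0, centroid=(0, 0),
                           mean_intensity={}, max_intensity={}, positive={})
        z.count_dna_maxima(empty, one, cfg)


def test_tabulate_hand_counts():
    """10 SAR11 + 2 infected + 1 zombie + 3 DNA-only: total 16, SAR11
    denominator 12 (infected cells are SAR11 cells)."""
    flag_sets = ([(True, True, False, 0.3)] * 10
                 + [(True, True, True, 0.3)] * 2
                 + [(True, False, True, 0.3)]
                 + [(True, False, False, 0.3)] * 3)
    objs = z.classify_objects([_obj(*f) for f in flag_sets], GATE)
    res = tabulate(objs, GATE)
    assert res.total_cells == 16
    assert res.sar11_cells == 12
    assert res.rel_infected == pytest.approx(2 / 12)
    assert res.rel_zombie == pytest.approx(1 / 16)
    assert res.undefined == ()


def test_tabulate_zero_denominators_flagged():
    objs = z.classify_objects([_obj(False, False, True, 0.03)], GATE)
    res = tabulate(objs, GATE)
    assert np.isnan(res.rel_infected) and np.isnan(res.rel_zombie)
    assert set(res.undefined) == {"rel_infected", "rel_zombie",
                                  "rel_sar11", "fdc"}


def test_tabulate_all_sar11_ratio_is_one():
    objs = z.classify_objects([_obj(True, True, False, 0.3)
                               for _ in range(5)], GATE)
    assert tabulate(objs, GATE).rel_sar11 == 1.0


def test_pooling_two_identical_fields(noisy_scene):
    spec, field, _ = noisy_scene
    cfg = z.calibrate_gates(spec)
    one = z.run_cytometry([field], cfg)
    two = z.run_cytometry([field, field], cfg)
    assert two.total_cells == 2 * one.total_cells
    assert two.infected_cells == 2 * one.infected_cells
    assert two.rel_infected == pytest.approx(one.rel_infected, nan_ok=True)
    with pytest.raises(ValueError):
        z.run_cytometry([], cfg)


def test_pooled_ratio_is_count_weighted_mean():
    spec_a = z.scene_for_fractions(40, infected_frac=0.5, sar11_frac=1.0,
                                   seed=1, field_shape=(420, 420))
    spec_b = z.scene_for_fractions(20, infected_frac=0.0, sar11_frac=1.0,
                                   seed=2, field_shape=(420, 420))
    cfg = z.calibrate_gates(spec_a)
    fa, _ = z.render_field(spec_a)
    fb, _ = z.render_field(spec_b)
    pooled = z.run_cytometry([fa, fb], cfg, count_dividing=False)
    ra = z.run_cytometry([fa], cfg, count_dividing=False)
    rb = z.run_cytometry([fb], cfg, count_dividing=False)
    expect = (ra.infected_cells + rb.infected_cells) / \
        (ra.sar11_cells + rb.sar11_cells)
    assert pooled.rel_infected == pytest.approx(expect)


def test_ground_truth_equivalence_noise_free(gates):
    """Noise-free, non-overlapping scenes: recovered class counts equal
    ground truth exactly (a slice of the larger acceptance sweep)."""
    for seed in range(10):
        spec = z.scene_for_fractions(
            n_cells=30, infected_frac=0.2, zombie_frac=0.1, sar11_frac=0.6,
            n_free_phage=4, dividing_fraction=0.1, seed=seed,
            field_shape=(380, 380), noise_sd=0.0)
        field, truth = z.render_field(spec)
        cfg = z.calibrate_gates(spec)
        res = z.run_cytometry([field], cfg)
        tc = truth["label"].value_counts()
        assert res.total_cells == 30
        assert res.sar11_cells == tc.get("uninfected_sar11", 0) + \
            tc.get("infected_sar11", 0)
        assert res.infected_cells == tc.get("infected_sar11", 0)
        assert res.zombie_cells == tc.get("zombie", 0)
        assert res.free_phage_objects == tc.get("free_phage", 0)
        assert res.dividing_cells == int(truth["dividing"].sum())


def test_threshold_monotonicity(noisy_scene):
    """Raising the phage threshold never increases infected + zombie."""
    spec, field, _ = noisy_scene
    cfg = z.calibrate_gates(spec)
    objs = z.segment_objects(field, cfg)
    base_thr = estimate_threshold(field.phage, cfg, "phage")
    prev = None
    for bump in (0.0, 10.0, 40.0, 120.0):
        n = 0
        for o in objs:
            flags = dict(o.positive)
            flags["phage"] = o.mean_intensity["phage"] > base_thr + bump
            o2 = _obj(flags["dna"], flags["rrna"], flags["phage"], o.area)
            lbl = z.classify_object(o2, cfg)
            n += lbl in ("infected_sar11", "zombie")
        if prev is not None:
            assert n <= prev
        prev = n


def test_area_gate_monotonicity(noisy_scene):
    """Raising free_phage_max_area never increases the zombie count."""
    spec, field, _ = noisy_scene
    cfg = z.calibrate_gates(spec)
    objs = z.segment_objects(field, cfg)
    prev = None
    for gate in (cfg.free_phage_max_area * f for f in (0.5, 1.0, 2.0, 5.0)):
        c = cfg.replace(free_phage_max_area=gate,
                        min_cell_area=gate * 1.01)
        n = sum(z.classify_object(o, c) == "zombie" for o in objs)
        if prev is not None:
            assert n <= prev
        prev = n


def test_negative_control_no_false_positives():
    spec = z.scene_for_fractions(60, infected_frac=0.3, zombie_frac=0.1,
                                 sar11_frac=0.6, seed=8,
                                 field_shape=(460, 460), noise_sd=0.0)
    cfg = z.calibrate_gates(spec)
    neg, _ = z.render_negative_control(spec)
    res = z.run_cytometry([neg], cfg, count_dividing=False)
    assert res.infected_cells == 0 and res.zombie_cells == 0


def test_fdc_recovers_dividing_fraction():
    """|FDC - d| within 3 binomial SEs at n >= 500 cells."""
    d = 0.12
    specs = [z.scene_for_fractions(120, sar11_frac=1.0, dividing_fraction=d,
                                   seed=s, field_shape=(740, 740))
             for s in range(5)]
    cfg = z.calibrate_gates(specs[0])
    fields = [z.render_field(s)[0] for s in specs]
    res = z.run_cytometry(fields, cfg)
    n = res.total_cells
    assert n >= 500
    se = np.sqrt(d * (1 - d) / n)
    assert abs(res.fdc - d) <= 3 * se


def test_eub_mode_counts_all_ribosomed_bacteria():
    """With an all-bacteria rRNA probe, other bacteria join the rRNA+ pool
    and probe-specific zombies remain rRNA-negative."""
    spec = z.scene_for_fractions(40, infected_frac=0.0, zombie_frac=0.1,
                                 sar11_frac=0.5, seed=9,
                                 field_shape=(420, 420),
                                 other_bacteria_rrna_amplitude=140.0)
    cfg = z.calibrate_gates(spec).replace(eub_mode=True)
    field, truth = z.render_field(spec)
    res = z.run_cytometry([field], cfg, count_dividing=False)
    n_rib = int((truth["rrna"]).sum())
    assert res.sar11_cells == n_rib          # rRNA+ now means "all bacteria"
    assert res.zombie_cells == int((truth["label"] == "zombie").sum())
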