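"""Interior-exterior classification: tasks, the nearest-centroid baseline
and the NumPy meta-learning backend."""

import numpy as np
import pytest

import tepals as tp
from tepals import _convnet as net
from tepals.errors import InvalidInputError
from tepals.ie_classifier import (
    FlowerPatches,
    MetaConfig,
    MetaTask,
    adapt_and_predict,
    baseline_predict,
    build_meta_training_task,
    flower_inventory,
    meta_train,
    upsample_patch,
)
from tepals.patches import Patch


def make_patch(pixels, label="unknown", slope_type=None):
    pixels = np.asarray(pixels, dtype=np.uint8)
    return Patch(
        pixels=pixels,
        center=(0.0, 0.0),
        orientation_angle=0.0,
        kind="synthetic",
        label=label,
        slope_type=slope_type,
        fg=pixels.sum(axis=2) > 0,
    )


def prototype_patch(side_with_edge="right"):
    """A patch whose interior color edge sits on one side below center."""
    px = np.zeros((20, 20, 3), dtype=np.uint8)
    px[8:, :] = (180, 60, 60)
    if side_with_edge == "right":
        px[10:, 15:] = (120, 140, 60)
    else:
        px[10:, :5] = (120, 140, 60)
    return px


@pytest.fixture(scope="module")
def tiny_pool():
    """A small pool of flowers with mixed L/R patterns for meta-tasks."""
    pool = []
    for i, (n, pattern) in enumerate([(6, "LRLRLR"), (5, "LLRLR"), (6, "LRLLRR")]):
        spec = tp.FlowerSpec(
            n_tepals=n, lr_pattern=pattern, canvas=(420, 280), seed=40 + i
        )
        image, truth = tp.render_flower(spec)
        pool.append(flower_inventory(image, truth, flower_id=f"f{i}", seed=i))
    return pool


# --- upsampling --------------------------------------------------------------


def test_upsample_shape_and_identity():
    p = make_patch(np.random.default_rng(0).integers(0, 255, (20, 20, 3)))
    up = upsample_patch(p, 84)
    assert up.shape == (84, 84, 3)
    same = upsample_patch(p, 20)
    assert np.array_equal(same, p.pixels.astype(np.float32))


def test_upsample_preserves_constants():
    p = make_patch(np.full((20, 20, 3), 77, dtype=np.uint8))
    up = upsample_patch(p, 84)
    assert np.allclose(up, 77.0, atol=1e-3)


def test_upsample_rejects_downscale():
    p = make_patch(np.zeros((20, 20, 3), dtype=np.uint8))
    with pytest.raises(InvalidInputError):
        upsample_patch(p, 10)


# --- task construction -------------------------------------------------------


def test_build_task_balanced_support_and_query(tiny_pool):
    task = build_meta_training_task(tiny_pool, seed=0)
    assert len(task.support) == 20
    labels = [l for _, l in task.support]
    assert labels.count("L") == labels.count("R") == 10
    assert len(task.query) == 2
    assert {l for _, l in task.query} == {"L", "R"}


def test_build_task_single_flower_seeds_differ(tiny_pool):
    t1 = build_meta_training_task(tiny_pool[:1], seed=1)
    t2 = build_meta_training_task(tiny_pool[:1], seed=2)
    p1 = {id(p) for p, _ in t1.support}
    p2 = {id(p) for p, _ in t2.support}
    assert p1 != p2  # different patch combinations from the same flower


def test_build_task_exhausted_pool_errors():
    empty = FlowerPatches(flower_id="x", synthetic=[], original=[])
    with pytest.raises(InvalidInputError):
        build_meta_training_task([empty], seed=0)


# --- baseline backend --------------------------------------------------------


def test_baseline_prototypes_confident():
    lp = make_patch(prototype_patch("left"), "R")
    rp = make_patch(prototype_patch("right"), "L")
    support = [(lp, "R"), (rp, "L")] * 5
    task = MetaTask(support=support, query=[(rp, None), (lp, None)])
    preds = baseline_predict(task)
    assert preds[0][0] == "L" and preds[0][1] > 0.9
    assert preds[1][0] == "R" and preds[1][1] > 0.9


def test_baseline_tie_breaks_to_L():
    """Identical support patches under both labels collapse the centroids,
    so every query is exactly equidistant: confidence 0.5, label L."""
    p = make_patch(prototype_patch("right"))
    task = MetaTask(support=[(p, "R"), (p, "L")] * 5, query=[(p, None)])
    label, conf = baseline_predict(task)[0]
    assert label == "L"
    assert conf == pytest.approx(0.5, abs=1e-9)


def test_baseline_label_symmetry(tiny_pool):
    task = build_meta_training_task(tiny_pool, seed=3)
    swapped = MetaTask(
        support=[(p, "L" if l == "R" else "R") for p, l in task.support],
        query=task.query,
    )
    orig = [l for l, _ in baseline_predict(task)]
    flip = [l for l, _ in baseline_predict(swapped)]
    assert flip == ["L" if l == "R" else "R" for l in orig]


def test_baseline_accuracy_on_renderer_tasks(tiny_pool):
    rng = np.random.default_rng(6)
    correct = total = 0
    for _ in range(25):
        task = build_meta_training_task(tiny_pool, rng)
        for (p, gt), (lab, conf) in zip(task.query, baseline_predict(task)):
            total += 1
            correct += lab == gt
            assert lab in ("L", "R")
            assert 0.0 <= conf <= 1.0
    assert correct / total > 0.7


# --- MAML backend ------------------------------------------------------------

TINY = MetaConfig(
    meta_iterations=8,
    meta_batch=2,
    input_side=24,
    channels=4,
    seed=0,
)


def test_meta_train_deterministic_and_finite(tiny_pool):
    m1 = meta_train(tiny_pool, TINY)
    m2 = meta_train(tiny_pool, TINY)
    for k in m1.params:
        assert np.array_equal(m1.params[k], m2.params[k])
        assert np.isfinite(m1.params[k]).all()


def test_adapt_memorizes_support_duplicate(tiny_pool):
    """A query that duplicates a support patch must get its support label
    after adaptation."""
    cfg = MetaConfig(
        meta_iterations=0,
        meta_batch=1,
        input_side=24,
        channels=8,
        inner_steps_eval=20,
        inner_lr=0.05,
        seed=1,
    )
    model = tp.IEModel(
        backend="maml",
        params=net.init_params(
            np.random.default_rng(1), channels=8, input_side=24
        ),
        config=cfg,
    )
    base = build_meta_training_task(tiny_pool, seed=4)
    dup_L = next(p for p, l in base.support if l == "L")
    dup_R = next(p for p, l in base.support if l == "R")
    task = MetaTask(support=base.support, query=[(dup_L, None), (dup_R, None)])
    preds = adapt_and_predict(model, task)
    assert preds[0][0] == "L"
    assert preds[1][0] == "R"


def test_meta_train_improves_over_init(tiny_pool):
    """A short run on easy high-contrast tasks beats an untrained
    initialization on held-out queries."""
    cfg = MetaConfig(
        meta_iterations=60, meta_batch=2, input_side=24, channels=8, seed=2
    )
    model = meta_train(tiny_pool, cfg)
    untrained = tp.IEModel(
        backend="maml",
        params=net.init_params(np.random.default_rng(2), channels=8, input_side=24),
        config=cfg,
    )

    def acc(m):
        rng = np.random.default_rng(9)
        hits = tot = 0
        for _ in range(15):
            task = build_meta_training_task(tiny_pool, rng)
            for (p, gt), (lab, _) in zip(task.query, adapt_and_predict(m, task)):
                tot += 1
                hits += lab == gt
        return hits / tot

    assert acc(model) >= acc(untrained)
    assert acc(model) > 0.6


def test_model_save_load_round_trip(tmp_path, tiny_pool):
    model = meta_train(tiny_pool, TINY)
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = tp.IEModel.load(path)
    assert loaded.backend == "maml"
    assert loaded.config == model.config
    task = build_meta_training_task(tiny_pool, seed=5)
    assert adapt_and_predict(loaded, task) == adapt_and_predict(model, task)


def test_predictions_well_formed(tiny_pool):
    task = build_meta_training_task(tiny_pool, seed=7)
    model = tp.IEModel(backend="baseline", params=None, config=TINY)
    preds = adapt_and_predict(model, task)
    assert len(preds) == len(task.query)
    for lab, conf in preds:
        assert lab in ("L", "R")
        assert 0.0 <= conf <= 1.0
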