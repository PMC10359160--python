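"""Self-contained desk-scale experiments on the synthetic phantom cohort.

These drive the full pipeline — phantom generation, training, synthesis,
evaluation — at sizes that run on a single CPU in minutes, and are the basis
of the package's verification suite.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import model
from .losses import image_similarity_loss
from .metrics import dsc
from .phantom import make_dataset
from .volumes import BinaryMask, VolumeGrid, warp_mask

__all__ = ["parameter_recovery", "desk_grid"]


def desk_grid(n: int = 48, spacing: float = 2.5) -> VolumeGrid:
    return VolumeGrid((n, n, n), (spacing,) * 3)


def _case_metrics(case, sct, dvf):
    """Held-out comparison of a synthesized volume against the planning state.

    Returns (lung DSC, masked L1 in HU) for the synthesis and for the
    unwarped baseline (the diagnostic volume itself).
    """
    lungs_p = case.masks_pct["lungs"]
    body = BinaryMask(case.dct.grid,
                      case.masks_dct["body"].values
                      | case.masks_pct["body"].values)
    warped_lungs = warp_mask(case.masks_dct["lungs"], dvf)
    dsc_model = dsc(warped_lungs, lungs_p)
    dsc_base = dsc(case.masks_dct["lungs"], lungs_p)
    # compare couch-free intensities: the couch is categorically different
    # between the two setups and is not part of the deformation task
    from .preprocess import remove_couch, segment_body

    pct_nc = remove_couch(case.pct, segment_body(case.pct))
    dct_nc = remove_couch(case.dct, segment_body(case.dct))
    l1_model = image_similarity_loss(sct, pct_nc, region=body)
    l1_base = image_similarity_loss(dct_nc, pct_nc, region=body)
    return {"dsc_model": dsc_model, "dsc_baseline": dsc_base,
            "l1_model": l1_model, "l1_baseline": l1_base}


def parameter_recovery(seed: int = 0, n_train: int = 8, n_test: int = 2,
                       epochs: int = 30, grid: VolumeGrid | None = None,
                       inference_integration_steps: int = 7) -> dict:
    """Train on phantom pairs and test deformation recovery on held-out cases.

    Training cases use seeds ``1000*seed .. 1000*seed + n_train - 1`` and the
    held-out cases the following ``n_test`` seeds, so train and test anatomy
    never coincide. Returns per-case held-out metrics plus the training
    history; success means the synthesized volumes beat the unwarped baseline
    on both lung-mask DSC and body-masked L1.
    """
    grid = grid or desk_grid()
    base = 1000 * seed
    train_cases = make_dataset(n_train, base_seed=base, grid=grid)
    test_cases = make_dataset(n_test, base_seed=base + n_train, grid=grid)
    cfg = model.desk_train_config(epochs=epochs, seed=seed)
    gen, _disc, history = model.train(train_cases, cfg)

    infer_cfg = replace(cfg,
                        n_integration_steps=inference_integration_steps)
    results = []
    for case in test_cases:
        from .preprocess import remove_couch, segment_body

        dct_nc = remove_couch(case.dct, segment_body(case.dct))
        sct, dvf = model.synthesize(gen, dct_nc, infer_cfg)
        m = _case_metrics(case, sct, dvf)
        m["max_displacement_mm"] = dvf.max_magnitude()
        results.append(m)

    mean = {k: float(np.mean([r[k] for r in results]))
            for k in ("dsc_model", "dsc_baseline", "l1_model", "l1_baseline")}
    return {
        "seed": seed,
        "per_case": results,
        "mean": mean,
        "improved_dsc": mean["dsc_model"] > mean["dsc_baseline"],
        "improved_l1": mean["l1_model"] < mean["l1_baseline"],
        "history": history,
    }
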