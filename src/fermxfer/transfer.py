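"""Transfer adaptation of a matched sub-source-domain model.

Adapts a pre-trained sigmoid network to a new (target) fermentation batch
with limited labels by:

* aligning hidden-layer feature distributions between source and target via
  the mean-embedding Maximum Mean Discrepancy,
  ``MMD = || mean(z_source) - mean(z_target) ||^2``;
* freezing the first ``k`` layers (learning rate 0 by default) while
  fine-tuning the remaining layers at a small learning rate on the joint
  objective ``L = MSE(target) + mmd_weight * MMD``;
* sequential output-side-first unfreezing with a validation stopping rule:
  one more layer is unfrozen only while it improves held-out target MSE by
  at least ``unfreeze_tol`` (relative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import network as nn

__all__ = [
    "TransferPlan",
    "extract_features",
    "mmd",
    "freeze_plan",
    "fine_tune",
    "sequential_unfreeze",
]


@dataclass(frozen=True)
class TransferPlan:
    """Layer freezing and fine-tuning schedule.

    ``frozen_depth`` counts layers from the input side that are held at
    ``lr_frozen`` (0 = true freeze); all deeper layers train at
    ``lr_finetune``.  ``feature_layer`` names the hidden layer whose
    activations feed the MMD term (default: last hidden layer).
    """

    frozen_depth: int = 0
    lr_frozen: float = 0.0
    lr_finetune: float = 1e-5
    epochs: int = 50
    mmd_weight: float = 1.0
    feature_layer: int | None = None
    unfreeze_tol: float = 1e-3
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.frozen_depth < 0:
            raise ValueError("frozen_depth must be >= 0")
        if self.lr_frozen < 0 or self.lr_finetune < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.lr_frozen > self.lr_finetune:
            raise ValueError("lr_frozen cannot exceed lr_finetune")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.mmd_weight < 0:
            raise ValueError("mmd_weight must be >= 0")


def extract_features(params: nn.NetworkParams, X: np.ndarray, layer: int
                     ) -> np.ndarray:
    """Activations of the given layer (1-based; n_layers = network output)."""
    L = params.arch.n_layers
    if not 1 <= layer <= L:
        raise ValueError(f"layer must be in [1, {L}]")
    _, activations = nn.forward(params, X)
    return activations[layer]


def mmd(Zs: np.ndarray, Zt: np.ndarray) -> float:
    """Squared distance between source and target feature means."""
    Zs = np.atleast_2d(np.asarray(Zs, dtype=float))
    Zt = np.atleast_2d(np.asarray(Zt, dtype=float))
    if Zs.shape[0] == 0 or Zt.shape[0] == 0:
        raise ValueError("feature sets must be nonempty")
    if Zs.shape[1] != Zt.shape[1]:
        raise ValueError("feature dimensions differ")
    diff = Zs.mean(axis=0) - Zt.mean(axis=0)
    return float(diff @ diff)


def freeze_plan(n_layers: int, k: int, plan: TransferPlan) -> np.ndarray:
    """Per-layer learning rates: first k layers frozen, the rest fine-tuned."""
    if not 0 <= k <= n_layers:
        raise ValueError(f"k must be in [0, {n_layers}]")
    rates = np.full(n_layers, plan.lr_finetune)
    rates[:k] = plan.lr_frozen
    return rates


def _feature_layer(plan: TransferPlan, arch: nn.NetworkArch) -> int:
    if plan.feature_layer is not None:
        return plan.feature_layer
    # default: last hidden layer (or the output layer for a 1-layer net)
    return max(arch.n_layers - 1, 1)


def fine_tune(params: nn.NetworkParams, source_X: np.ndarray,
              target_X: np.ndarray, target_Y: np.ndarray,
              plan: TransferPlan) -> tuple[nn.NetworkParams, list[tuple[float, float]]]:
    """Full-batch descent on MSE(target) + mmd_weight * MMD(source, target).

    ``source_X`` and ``target_X`` must already live in the source model's
    scaled input space, and ``target_Y`` in its scaled target space.
    Returns the adapted parameters and a per-epoch (mse, mmd) history.
    """
    target_X = np.atleast_2d(np.asarray(target_X, dtype=float))
    target_Y = np.atleast_2d(np.asarray(target_Y, dtype=float))
    if target_X.shape[0] == 0:
        raise ValueError("target data is empty")
    L = params.arch.n_layers
    lrs = freeze_plan(L, plan.frozen_depth, plan)
    f_layer = _feature_layer(plan, params.arch)
    n_t = target_X.shape[0]
    n_s = np.atleast_2d(source_X).shape[0]

    params = params.copy()
    history: list[tuple[float, float]] = []
    for epoch in range(plan.epochs):
        pred, act_t = nn.forward(params, target_X)
        delta_mse = 2.0 / (target_Y.shape[0] * target_Y.shape[1]) * (pred - target_Y)
        dW, db = nn.backprop_from(params, act_t, delta_mse, L)

        if plan.mmd_weight > 0:
            _, act_s = nn.forward(params, source_X)
            zs = act_s[f_layer]
            zt = act_t[f_layer]
            diff = zs.mean(axis=0) - zt.mean(axis=0)
            # d MMD / d z: +2 diff / n_s on source rows, -2 diff / n_t on target
            gs = np.broadcast_to(2.0 * diff / n_s, zs.shape)
            gt = np.broadcast_to(-2.0 * diff / n_t, zt.shape)
            dWs, dbs = nn.backprop_from(params, act_s, plan.mmd_weight * gs, f_layer)
            dWt, dbt = nn.backprop_from(params, act_t, plan.mmd_weight * gt, f_layer)
            dW = [a + b + c for a, b, c in zip(dW, dWs, dWt)]
            db = [a + b + c for a, b, c in zip(db, dbs, dbt)]

        params = nn.gd_step(params, (dW, db), lrs)
        pred_new, act_t_new = nn.forward(params, target_X)
        mse_val = nn.mse_loss(pred_new, target_Y)
        if not np.isfinite(mse_val):
            raise FloatingPointError(
                f"fine-tuning diverged at epoch {epoch + 1}")
        if plan.mmd_weight > 0:
            mmd_val = mmd(nn.forward(params, source_X)[1][f_layer],
                          act_t_new[f_layer])
        else:
            mmd_val = 0.0
        history.append((mse_val, mmd_val))
    return params, history


def sequential_unfreeze(params: nn.NetworkParams, source_X: np.ndarray,
                        target_X: np.ndarray, target_Y: np.ndarray,
                        plan: TransferPlan, seed: int = 0
                        ) -> tuple[nn.NetworkParams, int, dict]:
    """Output-side-first layer unfreezing with a validation stopping rule.

    Starts with everything but the output layer frozen, fine-tunes, then
    repeatedly unfreezes one more layer (toward the input) while the
    relative improvement in held-out target MSE stays above
    ``plan.unfreeze_tol``.  Returns the best-validation parameters, the
    frozen depth they correspond to, and a stage report.
    """
    target_X = np.atleast_2d(np.asarray(target_X, dtype=float))
    target_Y = np.atleast_2d(np.asarray(target_Y, dtype=float))
    n = target_X.shape[0]
    n_val = int(round(n * plan.val_fraction))
    if n_val < 1 or n - n_val < 1:
        raise ValueError(
            f"cannot split {n} target samples into train/validation "
            f"at val_fraction={plan.val_fraction}")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, Ytr = target_X[train_idx], target_Y[train_idx]
    Xval, Yval = target_X[val_idx], target_Y[val_idx]

    L = params.arch.n_layers
    stages: list[tuple[int, float]] = []

    def run_stage(p: nn.NetworkParams, k: int) -> tuple[nn.NetworkParams, float]:
        p2, _ = fine_tune(p, source_X, Xtr, Ytr, replace(plan, frozen_depth=k))
        return p2, nn.mse_loss(nn.forward(p2, Xval)[0], Yval)

    # the unadapted model is the baseline candidate: adaptation is kept
    # only where it actually improves held-out target error
    base_val = nn.mse_loss(nn.forward(params, Xval)[0], Yval)
    best_params, best_k, best_val = params, L, base_val

    k = L - 1  # output layer trains first
    current, val_mse = run_stage(params, k)
    stages.append((k, val_mse))
    if val_mse < best_val:
        best_params, best_k, best_val = current, k, val_mse

    while k > 0:
        cand, cand_val = run_stage(current, k - 1)
        improvement = (val_mse - cand_val) / max(val_mse, 1e-300)
        if improvement < plan.unfreeze_tol:
            break  # unfreezing one more layer no longer helps
        k -= 1
        current, val_mse = cand, cand_val
        stages.append((k, val_mse))
        if val_mse < best_val:
            best_params, best_k, best_val = current, k, val_mse

    report = {"stages": stages, "best_val_mse": best_val,
              "n_train": len(train_idx), "n_val": len(val_idx)}
    return best_params, best_k, report
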