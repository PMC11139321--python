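"""Desk-scale study protocol shared by the acceptance tests and script.

Eight synthetic chromosomes of 512 bins at 5-kb resolution are generated
under the default generator conditions: chrS1 is the blind-test
chromosome, chrS2..chrS7 train, chrS8 validates.  (Training on a single
chromosome memorizes its loop positions instead of learning the
amplification mapping, so the desk protocol uses several.)  Both the
regression U-Net and the diffusion model (base 16 channels, 64-bin tiles,
depth multipliers 1-2-4, 2-head 16-dim attention) are trained for small
fixed step budgets, then evaluated on the blind-test chromosome:
normalized L1 against the true Micro-C member, and truth-loop recovery via
the bundled dot detector at extending size 1.

Problem sizes and optimization budgets here are the package's desk-scale
defaults; the full-scale recipe lives in :mod:`contactdiff.pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .contact_io import ContactMatrix
from .denoiser_net import NetConfig
from .evaluation import LoopSet, recovery_fraction
from .pipeline import Checkpoint, TrainConfig, build_tile_store, predict_chromosome, train
from .preprocess import NormalizationSpec, TilingParams, normalize_forward
from .synthetic import SynthConfig, detect_dots, generate_study

#: desk-scale study conditions (fixed; see docs/methods.md)
DESK_NORM = NormalizationSpec(maxV=0.05, resolution=5000)
DESK_TILING = TilingParams(window=64, diag_step=48, max_right_steps=8)
DESK_NET = dict(window=64, base_channels=16, depth_multipliers=(1, 2, 4),
                attn_heads=2, attn_dim_head=16)
#: bounded desk-scale optimization budgets
DESK_REG_STEPS = 300
DESK_DDPM_STEPS = 400
DESK_LR = 2e-3
DESK_BATCH = 8       # regression
DESK_DDPM_BATCH = 4  # diffusion: smaller batches buy more optimizer steps
DESK_N_CHROMS = 8

TEST_CHROM, VAL_CHROM = "chrS1", "chrS8"


def normalized_l1(
    a: ContactMatrix,
    b: ContactMatrix,
    norm: NormalizationSpec = DESK_NORM,
    min_dist_bins: int = 1,
    max_dist_bins: Optional[int] = None,
) -> float:
    """Mean |a - b| on the normalized [-1, 1] scale over in-scope pixels."""
    if max_dist_bins is None:
        max_dist_bins = DESK_TILING.max_distance // a.resolution
    da = normalize_forward(a.to_dense(np.nan), norm)
    db = normalize_forward(b.to_dense(np.nan), norm)
    d = np.abs(np.subtract.outer(np.arange(a.n_bins), np.arange(a.n_bins)))
    mask = (np.isfinite(da) & np.isfinite(db)
            & (d >= min_dist_bins) & (d < max_dist_bins))
    return float(np.mean(np.abs(da[mask] - db[mask])))


def generate_desk_chromosomes(seed: int):
    """The study chromosomes (chrS1 = blind test, then train, last = val)."""
    cfg = SynthConfig(seed=seed % (2 ** 20))
    return generate_study(cfg, n_chroms=DESK_N_CHROMS)


def train_desk_models(
    study,
    seed: int,
    reg_steps: int = DESK_REG_STEPS,
    ddpm_steps: int = DESK_DDPM_STEPS,
) -> Tuple[Checkpoint, Checkpoint]:
    """Train regression and diffusion checkpoints on the desk tiles."""
    pairs = [(h, m) for h, m, _ in study[1:]]
    store = build_tile_store(pairs, DESK_NORM, DESK_TILING)
    common = dict(learning_rate=DESK_LR, val_max_tiles=16,
                  seed=seed % (2 ** 20))
    reg_cfg = TrainConfig(epochs=10_000, fixed_steps=reg_steps,
                          batch_size=DESK_BATCH, **common)
    ddpm_cfg = TrainConfig(epochs=10_000, fixed_steps=ddpm_steps,
                           batch_size=DESK_DDPM_BATCH, **common)
    reg = train("regression", store, reg_cfg,
                net_config=NetConfig(mode="regression", **DESK_NET),
                val_chroms=(VAL_CHROM,))
    ddpm = train("ddpm", store, ddpm_cfg,
                 net_config=NetConfig(mode="ddpm", **DESK_NET),
                 val_chroms=(VAL_CHROM,))
    return reg, ddpm


def truth_recovery(matrix: ContactMatrix, truth: LoopSet, s: int = 1) -> float:
    """Truth-loop recovery via the bundled dot detector."""
    return recovery_fraction(truth, detect_dots(matrix), s)
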