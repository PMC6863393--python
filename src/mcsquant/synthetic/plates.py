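"""Synthetic SGA colony plates with planted multiplicative effects.

Control colony size = plate effect x row effect x column effect x lognormal
noise; query plates additionally carry a per-gene interaction fitness factor
(factor < 1 = synthetic sick, factor 0 = synthetic lethal).  Sizes are
positive and all systematic effects multiplicative, matching how colony
growth artefacts behave on pinned 16 x 24 (384-spot) plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_ROWS = 16
N_COLS = 24


@dataclass
class PlateTruth:
    """Ground truth for one simulated screen (a 16 x 24 layout)."""

    genes: np.ndarray = None  # (16, 24) object array; None entries = empty well
    row_effects: np.ndarray = field(default_factory=lambda: np.ones(N_ROWS))
    col_effects: np.ndarray = field(default_factory=lambda: np.ones(N_COLS))
    plate_effects: np.ndarray = field(default_factory=lambda: np.ones(1))  # per replicate
    interaction_factors: dict = field(default_factory=dict)  # gene -> factor
    base_size: float = 100.0
    noise_sd: float = 0.0  # SD of ln(size) noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes is None:
            self.genes = np.array(
                [[f"g{r:02d}_{c:02d}" for c in range(N_COLS)] for r in range(N_ROWS)],
                dtype=object,
            )
        self.genes = np.asarray(self.genes, dtype=object)
        if self.genes.shape != (N_ROWS, N_COLS):
            raise ValueError(f"genes grid must be {N_ROWS} x {N_COLS}")
        self.row_effects = np.asarray(self.row_effects, dtype=float)
        self.col_effects = np.asarray(self.col_effects, dtype=float)
        self.plate_effects = np.atleast_1d(np.asarray(self.plate_effects, dtype=float))
        for name, eff in (
            ("row", self.row_effects),
            ("col", self.col_effects),
            ("plate", self.plate_effects),
        ):
            if (eff <= 0).any():
                raise ValueError(f"{name} effects must be positive")
        for g, f in self.interaction_factors.items():
            if f < 0:
                raise ValueError(f"interaction factor for {g!r} must be >= 0")


def _grid_to_frame(sizes: np.ndarray, genes: np.ndarray, plate_id: str) -> pd.DataFrame:
    rows, cols = np.meshgrid(np.arange(N_ROWS), np.arange(N_COLS), indexing="ij")
    return pd.DataFrame(
        {
            "plate": plate_id,
            "row": rows.ravel() + 1,
            "col": cols.ravel() + 1,
            "gene": genes.ravel(),
            "size": sizes.ravel(),
        }
    )


def gen_colony_experiment(
    truth: PlateTruth, n_plates: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate replicate query and control plates for one screen.

    Returns (query, control) tables in the plate CSV schema
    ``plate,row,col,gene,size``.  Replicate r uses plate effect
    ``plate_effects[r % len(plate_effects)]``; noise draws are independent
    between wells, replicates and the query/control arms.  Empty wells
    (gene None) get size 0 and are flagged downstream.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    rng = np.random.default_rng(truth.seed)
    base = truth.base_size * np.outer(truth.row_effects, truth.col_effects)
    factors = np.ones((N_ROWS, N_COLS))
    for r in range(N_ROWS):
        for c in range(N_COLS):
            g = truth.genes[r, c]
            if g is None:
                factors[r, c] = 0.0
            else:
                factors[r, c] = truth.interaction_factors.get(g, 1.0)

    query_frames, control_frames = [], []
    for p in range(n_plates):
        pe = truth.plate_effects[p % len(truth.plate_effects)]
        if truth.noise_sd > 0:
            noise_c = np.exp(rng.normal(0.0, truth.noise_sd, (N_ROWS, N_COLS)))
            noise_q = np.exp(rng.normal(0.0, truth.noise_sd, (N_ROWS, N_COLS)))
        else:
            noise_c = noise_q = 1.0
        control = base * pe * noise_c
        query = base * pe * factors * noise_q
        control[truth.genes == None] = 0.0  # noqa: E711 - elementwise None test
        query[truth.genes == None] = 0.0  # noqa: E711
        control_frames.append(_grid_to_frame(control, truth.genes, f"control_{p + 1}"))
        query_frames.append(_grid_to_frame(query, truth.genes, f"query_{p + 1}"))
    return pd.concat(query_frames, ignore_index=True), pd.concat(
        control_frames, ignore_index=True
    )
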