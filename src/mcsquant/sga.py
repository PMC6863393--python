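"""Synthetic genetic array (SGA) colony-size scoring.

Colony sizes from 16 x 24 (384-spot) plates are normalized per plate, row
and column by multiplicative median polish; per-gene interaction scores are
log2 ratios of mean normalized query size over mean normalized control size.
A score below -1.00 (strictly) -- colony growth reduced by more than a
factor of two -- calls a synthetic sick hit; a query gene with zero growth is
flagged lethal and scored -inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

N_ROWS = 16
N_COLS = 24

PLATE_COLUMNS = ["plate", "row", "col", "gene", "size"]

LETHAL = -np.inf


class PlateQualityError(ValueError):
    """Raised when a plate has too little growth to be normalized."""


@dataclass
class InteractionScore:
    gene: str
    score: float  # log2(query / control); -inf sentinel for lethal
    n_replicates: int
    hit: bool
    lethal: bool = False


def _check_plate_frame(df: pd.DataFrame) -> None:
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")


def _nonzero_median(values: np.ndarray) -> float:
    ok = values[np.isfinite(values) & (values > 0)]
    return float(np.median(ok)) if len(ok) else np.nan


def normalize_plate(
    plate: pd.DataFrame, max_iter: int = 25, tol: float = 1e-12
) -> pd.DataFrame:
    """Normalize one plate's colony sizes per plate, row and column.

    Sizes are divided by the plate median (over nonzero wells), then row and
    column medians are alternately divided out until the plate reaches a
    fixed point (multiplicative median polish).  The procedure is
    scale-invariant; it terminates at an exact fixed point -- and is then
    exactly idempotent -- whenever the plate decomposes into row/column
    effects plus a minority of outlier wells, and converges to tolerance
    otherwise (even-sized rows and columns make the interpolated median
    approach its fixed point only asymptotically under well-level noise).
    Zero or missing wells are excluded from every median and propagate with
    flag ``missing``.  Plates with fewer than 50% nonzero wells are
    rejected.
    """
    _check_plate_frame(plate)
    if plate["plate"].nunique() != 1:
        raise ValueError("normalize_plate expects a single plate")
    out = plate.copy()
    sizes = out["size"].to_numpy(dtype=float)
    grid = np.full((N_ROWS, N_COLS), np.nan)
    rows = out["row"].to_numpy(dtype=int) - 1
    cols = out["col"].to_numpy(dtype=int) - 1
    grid[rows, cols] = sizes
    ok = np.isfinite(grid) & (grid > 0)
    if ok.sum() < 0.5 * grid.size:
        raise PlateQualityError(
            f"plate {plate['plate'].iloc[0]!r}: fewer than 50% of wells grew"
        )

    work = grid.copy()
    work[~ok] = np.nan
    work /= _nonzero_median(work[ok])
    for _ in range(max_iter):
        row_med = np.nanmedian(work, axis=1)
        row_med[~np.isfinite(row_med)] = 1.0
        work /= row_med[:, None]
        col_med = np.nanmedian(work, axis=0)
        col_med[~np.isfinite(col_med)] = 1.0
        work /= col_med[None, :]
        if np.max(np.abs(row_med - 1.0)) < tol and np.max(np.abs(col_med - 1.0)) < tol:
            break

    normalized = work[rows, cols]
    normalized[~ok[rows, cols]] = 0.0
    out["size"] = normalized
    out["flag"] = np.where(ok[rows, cols], "ok", "missing")
    return out


def normalize_screen(tables: pd.DataFrame) -> pd.DataFrame:
    """Normalize every plate in a multi-plate table; bad plates are dropped."""
    _check_plate_frame(tables)
    frames = []
    for _, sub in tables.groupby("plate", sort=False):
        try:
            frames.append(normalize_plate(sub))
        except PlateQualityError:
            continue
    if not frames:
        raise PlateQualityError("no plate passed the growth threshold")
    return pd.concat(frames, ignore_index=True)


def interaction_scores(
    query: pd.DataFrame,
    control: pd.DataFrame,
    cutoff: float = -1.0,
    pseudo: float = 0.0,
    normalized: bool = False,
) -> list[InteractionScore]:
    """Per-gene log2 interaction scores of query vs control plates.

    Replicate wells of a gene are averaged (mean of normalized sizes) within
    each arm; score = log2((query mean + pseudo) / (control mean + pseudo)).
    A query mean of 0 is flagged lethal (score -inf sentinel, always a hit).
    Genes absent from the control arm are skipped.  Set ``normalized`` when
    the inputs have already been through :func:`normalize_screen`.
    """
    if not normalized:
        query = normalize_screen(query)
        control = normalize_screen(control)
    cmeans = control[control["gene"].notna()].groupby("gene")["size"].mean()
    scores = []
    for gene, sub in query[query["gene"].notna()].groupby("gene"):
        if gene not in cmeans.index or cmeans[gene] <= 0:
            continue
        qmean = sub["size"].mean()
        if qmean + pseudo <= 0:
            scores.append(
                InteractionScore(
                    gene=gene, score=LETHAL, n_replicates=len(sub), hit=True, lethal=True
                )
            )
            continue
        s = float(np.log2((qmean + pseudo) / (cmeans[gene] + pseudo)))
        scores.append(
            InteractionScore(
                gene=gene, score=s, n_replicates=len(sub), hit=bool(s < cutoff)
            )
        )
    return scores


def call_hits(scores: list[InteractionScore], cutoff: float = -1.0) -> set[str]:
    """Synthetic sick/lethal hits: score strictly below the cutoff.

    A score of exactly the cutoff is not a hit ("less than -1.00"); lethal
    sentinels always are.
    """
    return {s.gene for s in scores if s.lethal or s.score < cutoff}


def scores_frame(scores: list[InteractionScore], cutoff: float = -1.0) -> pd.DataFrame:
    """Scores as a gene,score,hit,lethal,n_replicates table."""
    hits = call_hits(scores, cutoff)
    return pd.DataFrame(
        {
            "gene": [s.gene for s in scores],
            "score": [s.score for s in scores],
            "hit": [s.gene in hits for s in scores],
            "lethal": [s.lethal for s in scores],
            "n_replicates": [s.n_replicates for s in scores],
        }
    ).sort_values("gene", ignore_index=True)


def rescue_matrix(
    base_scores: list[InteractionScore],
    per_construct_scores: dict[str, list[InteractionScore]],
    cutoff: float = -1.0,
) -> pd.DataFrame:
    """Genes x constructs score matrix; column ``none`` holds the base scores.

    A gene counts as rescued by a construct when its base score is below the
    cutoff but its score under the construct rises to the cutoff or above.
    The returned frame carries a boolean ``rescued_by_<construct>`` column
    per construct.
    """
    base = {s.gene: s.score for s in base_scores}
    out = pd.DataFrame({"gene": sorted(base), "none": [base[g] for g in sorted(base)]})
    for construct, scores in per_construct_scores.items():
        if construct == "none":
            raise ValueError("construct name 'none' is reserved for the base scores")
        smap = {s.gene: s.score for s in scores}
        out[construct] = [smap.get(g, np.nan) for g in out["gene"]]
        out[f"rescued_by_{construct}"] = (out["none"] < cutoff) & (out[construct] >= cutoff)
    return out.set_index("gene")
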