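"""2D embedding of per-compound descriptor-variability vectors.

Each compound is represented by the vector of per-descriptor standard
deviations across its top-k poses (standardised scale); embedding that
into the plane gives the interactive-map view of pose consistency.
Deterministic methods only — PCA and classical metric MDS — with the
method name recorded so a stochastic neighbour embedding can be slotted
in by callers who accept non-reproducible layouts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .consistency import ID_COLUMNS, StandardizationModel, fit_standardization

logger = logging.getLogger("posestab.embedding")

LABEL_COLORS = {"active": "red", "inactive": "black", "unknown": "gray", "ambiguous": "gray"}


@dataclass
class EmbeddingResult:
    coords: pd.DataFrame  # index compound_id, columns x, y
    method: str
    params: dict


def compound_std_vectors(
    table: pd.DataFrame,
    model: StandardizationModel | None = None,
    k: int | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-compound vectors of per-descriptor stds (standardised scale).

    ``table`` is the (compound, pose) descriptor table; ``k`` limits each
    compound to its first k rows.  Compounds with fewer than 2 poses are
    dropped; remaining NaNs (undefined descriptors) become 0 so all
    vectors share one dimension.
    """
    model = model or fit_standardization(table)
    sub = table.groupby("compound_id", sort=False).head(k) if k is not None else table
    counts = sub.groupby("compound_id", sort=False).size()
    sub = sub[sub["compound_id"].isin(counts[counts >= 2].index)]
    scaled = pd.concat([sub[["compound_id"]], model.transform(sub)], axis=1)
    vec = scaled.groupby("compound_id", sort=False)[model.retained].std(ddof=ddof)
    return vec.fillna(0.0)


def embed(vectors: pd.DataFrame, method: str = "pca") -> EmbeddingResult:
    """Deterministic 2D projection of the std vectors.

    "pca": top-2 principal axes.  "mds": classical (Torgerson) metric
    scaling of Euclidean distances, which coincides with PCA on centred
    Euclidean data up to rotation/reflection.  All-identical vectors
    degenerate to the origin with a warning.
    """
    if len(vectors) < 3:
        raise ValueError("embedding needs at least 3 vectors")
    x = np.asarray(vectors, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("std vectors must be finite")
    if np.allclose(x, x[0]):
        logger.warning("all vectors identical: embedding collapses to the origin")
        xy = np.zeros((len(x), 2))
    elif method == "pca":
        n_comp = min(2, min(x.shape))
        xy = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
        if xy.shape[1] < 2:
            xy = np.column_stack([xy, np.zeros(len(x))])
    elif method == "mds":
        xy = _classical_mds(x)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    coords = pd.DataFrame(xy, columns=["x", "y"], index=vectors.index)
    return EmbeddingResult(coords=coords, method=method, params={"n_components": 2})


def _classical_mds(x: np.ndarray) -> np.ndarray:
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=2)
    n = len(x)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:2]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def export_viz(
    embedding: EmbeddingResult,
    consistency: pd.DataFrame,
    path: str | Path,
    structures: Mapping[str, str] | None = None,
    fmt: str = "csv",
) -> pd.DataFrame:
    """Write the point map: coordinates, activity label and colour
    (red = active, black = inactive), consistency scores, and optional
    structure line notation per compound.

    ``consistency`` must hold one row per embedded compound (a single-k
    slice); ids present in the embedding but absent there are an error.
    """
    cons = consistency.set_index("compound_id")
    orphans = sorted(set(embedding.coords.index) - set(cons.index))
    if orphans:
        raise ValueError(f"no consistency record for embedded compounds: {orphans}")
    rows = cons.loc[embedding.coords.index]
    labels = rows["label"].fillna("unknown").replace("", "unknown")
    out = pd.DataFrame(
        {
            "x": embedding.coords["x"],
            "y": embedding.coords["y"],
            "compound_id": embedding.coords.index,
            "label": labels,
            "color": labels.map(lambda l: LABEL_COLORS.get(l, "gray")),
            "descriptor_std": rows["descriptor_std"],
            "atom_std": rows["atom_std"],
        }
    ).reset_index(drop=True)
    if structures is not None:
        out["smiles"] = out["compound_id"].map(structures)
    path = Path(path)
    if fmt == "csv":
        out.to_csv(path, index=False, float_format="%.10g")
    elif fmt == "jsonl":
        with path.open("w") as fh:
            for rec in out.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return out
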