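"""Pose-consistency statistics.

For every compound the descriptor table (one row per docked pose) is
reduced to a single pose-consistency score: the standard deviation of
each descriptor across the compound's top-k poses, averaged over
descriptors.  Because raw descriptor scales differ by orders of
magnitude (gravitational indexes in the thousands, shape indexes near
one), descriptors are z-standardised over the whole dataset first; a
raw-scale mode is kept for the per-descriptor summary.

The module also aggregates the score by activity class (the
actives-vs-inactives comparison), correlates it with rotatable-bond
counts, and ranks descriptors by their average variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import ensemble_atom_std
from .descriptors3d import ComputeConfig, descriptor_names, descriptor_table
from .model import ActivityRecord, PoseEnsemble, count_rotatable_bonds

logger = logging.getLogger("posestab.consistency")

DEFAULT_KS = (3, 5, 10)

ID_COLUMNS = ("compound_id", "pose_rank", "docking_score")


def select_top_k(ensemble: PoseEnsemble, k: int) -> PoseEnsemble:
    """Retain the min(k, available) best-scoring poses (ascending docking
    score, ties broken by file order).  Ensembles left with fewer than 2
    poses carry a skip flag instead of being dropped silently."""
    if k < 2:
        raise ValueError("k must be >= 2 for a standard deviation to exist")
    order = np.argsort(ensemble.docking_scores, kind="stable")[:k]
    order = np.sort(order)  # keep file order among the selected poses
    selected = PoseEnsemble(
        molecule=ensemble.molecule,
        poses=[ensemble.poses[i] for i in order],
        docking_scores=[ensemble.docking_scores[i] for i in order],
    )
    if selected.n_poses < 2:
        selected.skip_reason = f"only {selected.n_poses} pose(s) available"
    return selected


@dataclass
class StandardizationModel:
    """Per-descriptor z-scaling fitted over all (compound, pose) rows.

    Descriptors with vanishing variance or a majority of undefined
    entries are dropped (and recorded) rather than standardised to
    noise.
    """

    means: pd.Series
    stds: pd.Series
    dropped: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[str]:
        return list(self.means.index)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table[self.retained] - self.means) / self.stds

    def inverse_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return table[self.retained] * self.stds + self.means


def fit_standardization(
    table: pd.DataFrame,
    min_std: float = 1e-12,
    max_undefined_frac: float = 0.5,
) -> StandardizationModel:
    """Fit z-scaling parameters on a descriptor table (descriptor columns
    only; id columns are ignored if present)."""
    desc = table.drop(columns=[c for c in ID_COLUMNS if c in table.columns])
    if len(desc) < 2:
        raise ValueError("standardization needs at least 2 rows")
    nan_frac = desc.isna().mean()
    stds = desc.std(axis=0, ddof=0)
    dropped = sorted(desc.columns[(stds.fillna(0.0) < min_std) | (nan_frac > max_undefined_frac)])
    if dropped:
        logger.info("dropping %d descriptors (constant or mostly undefined)", len(dropped))
    keep = [c for c in desc.columns if c not in dropped]
    return StandardizationModel(means=desc[keep].mean(), stds=stds[keep], dropped=dropped)


def compound_descriptor_std(rows: pd.DataFrame, ddof: int = 0) -> float:
    """Mean over descriptors of the per-descriptor std across one
    compound's selected poses.  Undefined entries are excluded per
    descriptor; descriptors with fewer than 2 defined values contribute
    nothing.  Returns NaN when no descriptor is usable."""
    desc = rows.drop(columns=[c for c in ID_COLUMNS if c in rows.columns])
    if len(desc) < 2:
        raise ValueError("need at least 2 poses")
    stds = desc.std(axis=0, ddof=ddof)
    usable = desc.notna().sum(axis=0) >= 2
    stds = stds[usable & stds.notna()]
    if stds.empty:
        return float("nan")
    return float(stds.mean())


@dataclass
class ConsistencyConfig:
    ks: Sequence[int] = DEFAULT_KS
    ddof: int = 0                 # population std, switchable to sample (1)
    standardize: bool = True
    compute: ComputeConfig = field(default_factory=ComputeConfig)


@dataclass
class ConsistencyResults:
    consistency: pd.DataFrame      # one row per compound x k
    groups: pd.DataFrame           # activity-class aggregation per k
    correlations: pd.DataFrame     # rotatable-bond Pearson r per k
    per_descriptor: pd.DataFrame   # per-descriptor mean std, sorted
    skipped: pd.DataFrame          # compounds excluded, with reasons
    descriptors: pd.DataFrame      # raw descriptor table (compound x pose)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.consistency.to_csv(outdir / "consistency.csv", index=False, float_format=fmt)
        self.groups.to_csv(outdir / "groups.csv", index=False, float_format=fmt)
        self.correlations.to_csv(outdir / "correlations.csv", index=False, float_format=fmt)
        self.per_descriptor.to_csv(outdir / "per_descriptor.csv", index=False, float_format=fmt)
        self.skipped.to_csv(outdir / "skipped.csv", index=False)
        self.descriptors.to_csv(outdir / "descriptors.csv", index=False, float_format=fmt)


def analyze(
    ensembles: Sequence[PoseEnsemble],
    activities: Iterable[ActivityRecord] | Mapping[str, str] | None = None,
    config: ConsistencyConfig | None = None,
) -> ConsistencyResults:
    """Full pose-consistency analysis of a set of ensembles.

    Computes the descriptor table once, standardises it, and for every
    k in ``config.ks`` derives the per-compound descriptor-std score and
    atom-position RMSF, then the group summaries, rotatable-bond
    correlations and the per-descriptor variability ranking.
    """
    config = config or ConsistencyConfig()
    labels = _label_map(activities)

    table = descriptor_table(ensembles, config.compute)
    model = fit_standardization(table)
    scaled = pd.concat(
        [table[list(ID_COLUMNS)], model.transform(table)], axis=1
    ) if config.standardize else table

    records, skipped = [], []
    for ens in ensembles:
        n_rot = count_rotatable_bonds(ens.molecule)
        label = labels.get(ens.compound_id, "unknown")
        for k in config.ks:
            sel = select_top_k(ens, k)
            if sel.skip_reason is not None:
                skipped.append({"compound_id": ens.compound_id, "k": k, "reason": sel.skip_reason})
                continue
            mask = (scaled["compound_id"] == ens.compound_id) & scaled["pose_rank"].isin(
                _selected_ranks(ens, k)
            )
            dstd = compound_descriptor_std(scaled.loc[mask], ddof=config.ddof)
            if not np.isfinite(dstd):
                skipped.append({"compound_id": ens.compound_id, "k": k, "reason": "all descriptors undefined"})
                continue
            astd = ensemble_atom_std(ens, k=k, ddof=config.ddof).compound_mean
            records.append(
                {
                    "compound_id": ens.compound_id,
                    "k": k,
                    "n_poses_used": sel.n_poses,
                    "descriptor_std": dstd,
                    "atom_std": astd,
                    "n_rot": n_rot,
                    "label": label,
                }
            )
    consistency = pd.DataFrame(
        records,
        columns=["compound_id", "k", "n_poses_used", "descriptor_std", "atom_std", "n_rot", "label"],
    )
    skipped_df = pd.DataFrame(skipped, columns=["compound_id", "k", "reason"])
    groups = summarize_groups(consistency)
    correlations = _correlation_table(consistency, config.ks)
    per_desc = per_descriptor_std_summary(table, model, k=max(config.ks), ddof=config.ddof)
    return ConsistencyResults(
        consistency=consistency,
        groups=groups,
        correlations=correlations,
        per_descriptor=per_desc,
        skipped=skipped_df,
        descriptors=table,
    )


def _selected_ranks(ensemble: PoseEnsemble, k: int) -> list[int]:
    return sorted(np.argsort(ensemble.docking_scores, kind="stable")[:k].tolist())


def _label_map(activities) -> dict[str, str]:
    if activities is None:
        return {}
    if isinstance(activities, Mapping):
        return dict(activities)
    return {rec.compound_id: rec.label for rec in activities}


def summarize_groups(consistency: pd.DataFrame, extra_keys: Sequence[str] = ()) -> pd.DataFrame:
    """Mean consistency statistics for actives vs inactives per k (plus
    optional extra grouping keys, e.g. a dataset column), with an
    actives-higher indicator per statistic.  Groups with no compounds
    are reported as missing, never as zero."""
    labelled = consistency[consistency["label"].isin(["active", "inactive"])]
    keys = list(extra_keys) + ["k"]
    rows = []
    for key_vals, sub in labelled.groupby(keys):
        key_vals = key_vals if isinstance(key_vals, tuple) else (key_vals,)
        row = dict(zip(keys, key_vals))
        for label in ("active", "inactive"):
            grp = sub[sub["label"] == label]
            row[f"{label}_descriptor_std"] = grp["descriptor_std"].mean() if len(grp) else np.nan
            row[f"{label}_atom_std"] = grp["atom_std"].mean() if len(grp) else np.nan
            row[f"n_{label}"] = len(grp)
        for stat in ("descriptor_std", "atom_std"):
            a, i = row[f"active_{stat}"], row[f"inactive_{stat}"]
            row[f"actives_higher_{stat}"] = bool(a > i) if np.isfinite(a) and np.isfinite(i) else None
        rows.append(row)
    return pd.DataFrame(rows)


def rotbond_correlation(consistency: pd.DataFrame) -> float:
    """Pearson correlation between rotatable-bond count and the
    descriptor-std score over all labelled and unlabelled compounds.
    NaN when either variable has no variance or fewer than 3 records."""
    sub = consistency[["n_rot", "descriptor_std"]].dropna()
    if len(sub) < 3 or sub["n_rot"].nunique() < 2 or sub["descriptor_std"].nunique() < 2:
        return float("nan")
    r, _ = stats.pearsonr(sub["n_rot"], sub["descriptor_std"])
    return float(r)


def _correlation_table(consistency: pd.DataFrame, ks: Sequence[int]) -> pd.DataFrame:
    rows = []
    for k in ks:
        sub = consistency[consistency["k"] == k]
        rows.append({"k": k, "pearson_r": rotbond_correlation(sub), "n_compounds": len(sub)})
    return pd.DataFrame(rows, columns=["k", "pearson_r", "n_compounds"])


def per_descriptor_std_summary(
    table: pd.DataFrame,
    model: StandardizationModel | None = None,
    k: int | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Per-descriptor variability: std across poses per compound,
    averaged over compounds, on the raw and the standardised scale;
    sorted ascending by the standardised value.

    ``k`` limits each compound to its first k rows of the table (the
    table is already pose-rank ordered); None uses all poses.
    """
    model = model or fit_standardization(table)
    ids = table["compound_id"]
    desc_cols = [c for c in table.columns if c not in ID_COLUMNS]
    sub = table.groupby("compound_id", sort=False).head(k) if k is not None else table
    counts = sub.groupby("compound_id", sort=False).size()
    keep_ids = counts[counts >= 2].index
    sub = sub[sub["compound_id"].isin(keep_ids)]

    raw_std = sub.groupby("compound_id", sort=False)[desc_cols].std(ddof=ddof).mean(axis=0)
    scaled = pd.concat([sub[["compound_id"]], model.transform(sub)], axis=1)
    std_std = scaled.groupby("compound_id", sort=False)[model.retained].std(ddof=ddof).mean(axis=0)

    out = pd.DataFrame(
        {
            "descriptor": desc_cols,
            "raw_mean_std": raw_std.reindex(desc_cols).values,
            "standardized_mean_std": std_std.reindex(desc_cols).values,
        }
    )
    out["dropped"] = out["descriptor"].isin(model.dropped)
    return out.sort_values(
        "standardized_mean_std", na_position="last", kind="stable"
    ).reset_index(drop=True)
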