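"""Reference-anchored nearest-neighbour colocalization and intensity summaries.

The reference point set is the mature-capsid immunostain channel; each
reference detection is paired with its nearest query-channel detection and
the pair counts as colocalized when the centroids lie strictly within the
distance threshold (0.500 um by default, 2-D Euclidean on projected images).
Matching is reference-anchored: a query detection may serve several
references (many-to-one); an optional strict one-to-one mode assigns pairs
greedily by ascending distance.  Chance colocalization from particle density
alone is quantified by re-drawing query positions uniformly over the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from statsmodels.stats.proportion import proportion_confint

from .detect import DetectionTable

__all__ = [
    "ColocResult",
    "pair_to_reference",
    "colocalized_fraction",
    "chance_colocalization",
    "colocalize",
    "intensity_summary",
]

DEFAULT_THRESHOLD_UM = 0.500


@dataclass
class ColocResult:
    """Colocalized fraction of reference detections, with provenance."""

    reference_channel: str | None
    query_channel: str | None
    threshold_um: float
    n_reference: int
    n_paired: int
    fraction: float
    ci_low: float
    ci_high: float
    pairs: pd.DataFrame  # columns: ref_id, query_id, distance_um
    null_fractions: np.ndarray | None = None
    null_mean: float | None = None
    meta: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "reference_channel": self.reference_channel,
            "query_channel": self.query_channel,
            "threshold_um": self.threshold_um,
            "n_reference": self.n_reference,
            "n_paired": self.n_paired,
            "fraction": self.fraction,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "null_mean": self.null_mean,
        }
        d.update(self.meta)
        return d


def _positions(table) -> np.ndarray:
    if isinstance(table, DetectionTable):
        return table.positions_um
    return np.asarray(table, dtype=float)


def pair_to_reference(
    reference,
    query,
    threshold_um: float = DEFAULT_THRESHOLD_UM,
    one_to_one: bool = False,
) -> pd.DataFrame:
    """Nearest-neighbour pairs from each reference detection to the query set.

    Accepts DetectionTables or raw (n, 2) um coordinate arrays.  Returns a
    DataFrame (ref_id, query_id, distance_um) keeping only pairs strictly
    closer than ``threshold_um``.  With ``one_to_one`` each query detection
    is consumed by at most one reference, assigned greedily by ascending
    distance.
    """
    if threshold_um <= 0:
        raise ValueError("threshold_um must be > 0")
    if (
        isinstance(reference, DetectionTable)
        and isinstance(query, DetectionTable)
        and not np.isclose(reference.pixel_size_um, query.pixel_size_um)
    ):
        raise ValueError("reference and query tables have different pixel calibrations")
    ref = _positions(reference)
    qry = _positions(query)
    if len(ref) == 0:
        raise ValueError("empty reference table: colocalized fraction undefined")
    empty = pd.DataFrame({"ref_id": pd.Series(dtype=int), "query_id": pd.Series(dtype=int), "distance_um": pd.Series(dtype=float)})
    if len(qry) == 0:
        return empty

    tree = cKDTree(qry)
    if not one_to_one:
        dist, idx = tree.query(ref)
        keep = dist < threshold_um
        return pd.DataFrame(
            {
                "ref_id": np.nonzero(keep)[0],
                "query_id": idx[keep],
                "distance_um": dist[keep],
            }
        )

    # strict one-to-one: greedy by ascending distance over all close pairs
    cand = tree.query_ball_point(ref, threshold_um)
    triples = [
        (float(np.hypot(*(ref[i] - qry[j]))), i, j)
        for i, js in enumerate(cand)
        for j in js
    ]
    triples.sort()
    used_ref: set[int] = set()
    used_qry: set[int] = set()
    rows = []
    for d, i, j in triples:
        if d >= threshold_um or i in used_ref or j in used_qry:
            continue
        used_ref.add(i)
        used_qry.add(j)
        rows.append({"ref_id": i, "query_id": j, "distance_um": d})
    return pd.DataFrame(rows, columns=["ref_id", "query_id", "distance_um"]) if rows else empty


def colocalized_fraction(pairs: pd.DataFrame, n_reference: int) -> tuple[float, float, float]:
    """Fraction of references paired, with a Wilson 95% binomial interval."""
    if n_reference < 1:
        raise ValueError("n_reference must be >= 1")
    n_paired = int(pairs["ref_id"].nunique()) if len(pairs) else 0
    lo, hi = proportion_confint(n_paired, n_reference, alpha=0.05, method="wilson")
    return n_paired / n_reference, float(lo), float(hi)


def chance_colocalization(
    reference,
    query,
    field_bounds_um: tuple[float, float],
    n_shuffles: int = 100,
    seed: int = 0,
    threshold_um: float = DEFAULT_THRESHOLD_UM,
) -> np.ndarray:
    """Null colocalized fractions from uniformly re-drawn query positions.

    Query positions are resampled uniformly over the field ``n_shuffles``
    times and the fraction recomputed with toroidal (wrap-around) distances,
    so the null matches the Poisson closed form 1 - exp(-lambda pi r^2)
    without edge losses.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    ref = _positions(reference)
    qry = _positions(query)
    w, h = field_bounds_um
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_shuffles)
    for s in range(n_shuffles):
        if len(qry) == 0:
            fractions[s] = 0.0
            continue
        resampled = rng.uniform([0, 0], [w, h], size=(len(qry), 2))
        # 3x3 tiling implements the toroidal metric for r << field size
        shifts = np.array([(dx, dy) for dx in (-w, 0, w) for dy in (-h, 0, h)])
        tiled = (resampled[None, :, :] + shifts[:, None, :]).reshape(-1, 2)
        dist, _ = cKDTree(tiled).query(ref)
        fractions[s] = float(np.mean(dist < threshold_um))
    return fractions


def colocalize(
    reference: DetectionTable,
    query: DetectionTable,
    threshold_um: float = DEFAULT_THRESHOLD_UM,
    one_to_one: bool = False,
    edge_correction: bool = True,
    n_shuffles: int = 0,
    seed: int = 0,
) -> ColocResult:
    """Full reference-anchored colocalization of two detection tables.

    With ``edge_correction`` reference detections within ``threshold_um`` of
    the field border are dropped from the denominator (their neighbourhood
    is censored by the field edge).  ``n_shuffles > 0`` adds a uniform-
    resampling null (see :func:`chance_colocalization`).
    """
    ref_pos = reference.positions_um
    if len(ref_pos) == 0:
        raise ValueError("empty reference table: colocalized fraction undefined")
    bounds = reference.field_bounds_um
    n_edge_excluded = 0
    if edge_correction:
        if bounds is None:
            raise ValueError("edge correction requires field bounds on the reference table")
        w, h = bounds
        interior = (
            (ref_pos[:, 0] >= threshold_um)
            & (ref_pos[:, 0] <= w - threshold_um)
            & (ref_pos[:, 1] >= threshold_um)
            & (ref_pos[:, 1] <= h - threshold_um)
        )
        n_edge_excluded = int((~interior).sum())
        ref_pos = ref_pos[interior]
        if len(ref_pos) == 0:
            raise ValueError("edge correction removed every reference detection")

    pairs = pair_to_reference(ref_pos, query, threshold_um, one_to_one=one_to_one)
    fraction, lo, hi = colocalized_fraction(pairs, len(ref_pos))

    null_fracs = None
    null_mean = None
    if n_shuffles > 0:
        if bounds is None:
            raise ValueError("the null requires field bounds on the reference table")
        null_fracs = chance_colocalization(
            ref_pos, query, bounds, n_shuffles=n_shuffles, seed=seed, threshold_um=threshold_um
        )
        null_mean = float(null_fracs.mean())

    return ColocResult(
        reference_channel=reference.channel,
        query_channel=query.channel,
        threshold_um=threshold_um,
        n_reference=len(ref_pos),
        n_paired=int(pairs["ref_id"].nunique()) if len(pairs) else 0,
        fraction=fraction,
        ci_low=lo,
        ci_high=hi,
        pairs=pairs,
        null_fractions=null_fracs,
        null_mean=null_mean,
        meta={
            "one_to_one": one_to_one,
            "edge_correction": edge_correction,
            "n_edge_excluded": n_edge_excluded,
        },
    )


def intensity_summary(
    tables: dict[str, DetectionTable],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-construct single-particle intensity summary with bootstrap CIs.

    Returns ``(summary, ratios)``: per construct the detection count, median
    and mean mass with a bootstrap 95% interval on the median (ordered by
    median mass, brightest first), and the pairwise median-mass ratios
    between named constructs with bootstrap intervals.
    """
    rng = np.random.default_rng(seed)
    boot_medians: dict[str, np.ndarray] = {}
    rows = []
    for name, table in tables.items():
        masses = table.df["mass"].to_numpy(dtype=float)
        if masses.size == 0:
            raise ValueError(f"construct {name!r} has no detections")
        bm = np.median(
            masses[rng.integers(0, masses.size, size=(n_boot, masses.size))], axis=1
        )
        boot_medians[name] = bm
        rows.append(
            {
                "construct": name,
                "n": masses.size,
                "median_mass": float(np.median(masses)),
                "mean_mass": float(masses.mean()),
                "median_ci_low": float(np.percentile(bm, 2.5)),
                "median_ci_high": float(np.percentile(bm, 97.5)),
            }
        )
    summary = (
        pd.DataFrame(rows).sort_values("median_mass", ascending=False).reset_index(drop=True)
    )

    names = list(tables)
    ratio_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            br = boot_medians[a] / boot_medians[b]
            ratio_rows.append(
                {
                    "numerator": a,
                    "denominator": b,
                    "median_ratio": float(
                        np.median(tables[a].df["mass"]) / np.median(tables[b].df["mass"])
                    ),
                    "ratio_ci_low": float(np.percentile(br, 2.5)),
                    "ratio_ci_high": float(np.percentile(br, 97.5)),
                }
            )
    ratios = pd.DataFrame(
        ratio_rows,
        columns=["numerator", "denominator", "median_ratio", "ratio_ci_low", "ratio_ci_high"],
    )
    return summary, ratios
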