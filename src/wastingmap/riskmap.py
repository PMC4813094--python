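"""WHO severity classification and population-weighted burden aggregation.

Predicted prevalence surfaces are classified into the five WHO wasting
severity bands and multiplied by an under-five population grid to give the
expected number of wasted children per pixel, summed by zone, year-season
and severity class.  Also reproduces the descriptive per-region survey
summary from cluster records.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: WHO wasting severity classes.  The paper's source guide writes
#: "15-20%" for critical and ">20%" for very critical, which closes the
#: critical interval at exactly 20%.
WHO_CLASSES = ("acceptable", "alert", "serious", "critical", "very_critical")
_WHO_EDGES = (0.05, 0.10, 0.15, 0.20)

SEASONS = ("Jilaal", "Gu", "Hagaa", "Deyr")
DRY_SEASONS = ("Jilaal", "Hagaa")
WET_SEASONS = ("Gu", "Deyr")


def classify_who(prevalence):
    """Map prevalence in [0, 1] to a WHO severity class.

    Intervals: [0,0.05) acceptable, [0.05,0.10) alert, [0.10,0.15) serious,
    [0.15,0.20] critical, (0.20,1] very_critical.  Scalar in, scalar out;
    array in, object array out.
    """
    p = np.asarray(prevalence, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("prevalence must lie in [0, 1]")
    idx = np.searchsorted(_WHO_EDGES, p, side="right")
    # searchsorted(side="right") puts 0.20 in very_critical; the WHO band
    # "15-20%" is closed at 0.20, so pull exact-boundary points back
    idx = np.where(p == 0.20, 3, idx)
    out = np.array(WHO_CLASSES, dtype=object)[np.atleast_1d(idx)]
    if np.ndim(prevalence) == 0:
        return out[0]
    return out


@dataclass
class RiskTable:
    """Zone x year-season x WHO-class expected counts of wasted children."""

    table: pd.DataFrame  # zone, year, season, who_class, wasted_count
    total: float

    def formatted(self, mask_below: int = 50) -> pd.DataFrame:
        """Report-style table with counts below ``mask_below`` shown as
        ``<50`` (the raw values stay available in ``table``)."""
        out = self.table.copy()
        rounded = np.floor(out["wasted_count"] + 0.5).astype(int)
        out["wasted_count"] = [
            f"<{mask_below}" if r < mask_below else f"{r:,}" for r in rounded
        ]
        return out


def wasted_children_counts(prevalence_grids, population_grid, zones) -> RiskTable:
    """Expected wasted children per (zone, year, season, WHO class).

    ``prevalence_grids`` maps (year, season) -> prevalence Grid aligned with
    ``population_grid``; ``zones`` maps zone name -> shapely polygon.  Every
    populated pixel must fall in exactly one zone.  Counts are kept
    real-valued (expectations); rounding and the "<50" convention are
    formatting concerns.
    """
    import shapely

    pop = population_grid
    px, py = pop.centers()
    pop_vals = pop.values.ravel()

    zone_of = np.full(pop_vals.size, -1, dtype=int)
    zone_names = list(zones)
    for zi, name in enumerate(zone_names):
        inside = shapely.contains_xy(zones[name], px, py)
        zone_of[inside & (zone_of < 0)] = zi
    orphans = np.flatnonzero((zone_of < 0) & (pop_vals > 0))
    if orphans.size:
        raise ValueError(
            f"populated pixels outside every zone at flat indices: "
            f"{orphans[:20].tolist()}"
        )

    rows = []
    grand_total = 0.0
    for (year, season), grid in prevalence_grids.items():
        if not grid.same_geometry(pop):
            raise ValueError(f"grid geometry mismatch at ({year}, {season})")
        prev = grid.values.ravel()
        valid = np.isfinite(prev) & (pop_vals > 0)
        expected = np.where(valid, prev * pop_vals, 0.0)
        cls = np.full(prev.size, "", dtype=object)
        cls[valid] = classify_who(prev[valid])
        for zi, zone in enumerate(zone_names):
            for who in WHO_CLASSES:
                sel = valid & (zone_of == zi) & (cls == who)
                count = float(expected[sel].sum())
                rows.append(
                    {
                        "zone": zone,
                        "year": year,
                        "season": season,
                        "who_class": who,
                        "wasted_count": count,
                    }
                )
                grand_total += count
    return RiskTable(table=pd.DataFrame(rows), total=grand_total)


def load_table1_fixture() -> pd.DataFrame:
    """Packaged per-region survey summary (18 region rows)."""
    with resources.files("wastingmap.data").joinpath("table1_fsnau.csv").open() as f:
        return pd.read_csv(f)


def summarize_table1(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-region descriptive table (clusters, examined, wasted, percent)
    with a totals row.

    Accepts either region-aggregated rows (with an ``n_clusters`` column)
    or cluster-level records carrying a ``region`` column, in which case
    each row counts as one cluster.
    """
    if observations.empty:
        raise ValueError("no observations to summarize")
    df = observations.copy()
    if "region" not in df.columns:
        raise KeyError("observations need a 'region' column")
    if "n_clusters" not in df.columns:
        df["n_clusters"] = 1
    grouped = (
        df.groupby("region", sort=False)[["n_clusters", "n_examined", "n_wasted"]]
        .sum()
        .reset_index()
    )
    zero = grouped["n_examined"] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * grouped["n_wasted"] / grouped["n_examined"]
    grouped["percent_wasted"] = pct.round(2)
    grouped.loc[zero, "percent_wasted"] = np.nan
    grouped["percent_undefined"] = zero

    tot_ex = int(grouped["n_examined"].sum())
    tot_w = int(grouped["n_wasted"].sum())
    totals = pd.DataFrame(
        [
            {
                "region": "Total",
                "n_clusters": int(grouped["n_clusters"].sum()),
                "n_examined": tot_ex,
                "n_wasted": tot_w,
                "percent_wasted": round(100.0 * tot_w / tot_ex, 2)
                if tot_ex
                else np.nan,
                "percent_undefined": tot_ex == 0,
            }
        ]
    )
    return pd.concat([grouped, totals], ignore_index=True)


def dry_wet_difference(prevalence_grids, year):
    """Per-pixel mean dry-season minus mean wet-season prevalence for a year.

    Dry = mean of Jilaal and Hagaa surfaces; wet = mean of Gu and Deyr.
    """
    dry = [prevalence_grids[(year, s)].values for s in DRY_SEASONS]
    wet = [prevalence_grids[(year, s)].values for s in WET_SEASONS]
    ref = prevalence_grids[(year, DRY_SEASONS[0])]
    return ref.with_values(np.mean(dry, axis=0) - np.mean(wet, axis=0))
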