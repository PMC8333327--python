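"""From per-object imaging tables to community metrics.

Each imaged organism carries the major and minor axes of its best-fitting
ellipse; its equivalent spherical diameter (ESD) is the diameter of the
circle with the same area, ``sqrt(major * minor)`` -- the standard ZooScan
convention (the size proxy every downstream result depends on).  Objects
roll up through the nested taxon registry so that a Calanidae individual
counts in Calanidae, Calanoida, Copepoda and total Zooplankton.  Per
station x group x net we report abundance (count / filtered volume, ind m-3)
and, when at least ``min_n`` individuals were measured, the median ESD.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import ROOT, UNIDENTIFIED_BUCKETS, TaxonRegistry

log = logging.getLogger(__name__)

MIN_N_INDIVIDUALS = 20     # median ESD requires at least this many measured
MIN_STATIONS = 30          # a (group, net) enters modelling at >= this many

OBJECT_COLUMNS = ["object_id", "station_id", "net_id", "taxon",
                  "ellipse_major_um", "ellipse_minor_um"]

#: latitudinal band edges; stations at exactly 30 or 60 go to the lower band
BANDS = {"tropical": (0.0, 30.0), "temperate": (30.0, 60.0),
         "polar": (60.0, 90.0)}


def compute_esd(major_um, minor_um):
    """Area-equivalent ESD of an ellipse: sqrt(major * minor), in um."""
    major = np.asarray(major_um, float)
    minor = np.asarray(minor_um, float)
    if np.any(major <= 0) or np.any(minor <= 0):
        raise ValueError("ellipse axes must be positive")
    out = np.sqrt(major * minor)
    return float(out) if out.ndim == 0 else out


def read_object_table(path: str | Path, samples_path: str | Path,
                      ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Read an Ecotaxa-flavoured object TSV and its sample-volume CSV.

    Returns the object table with ``esd_um`` computed on read, and a
    station -> filtered volume (m3) map.  Unknown columns are ignored with
    a warning; missing mandatory columns and non-positive axes are errors.
    """
    obj = pd.read_csv(path, sep="\t")
    missing = [c for c in OBJECT_COLUMNS if c not in obj.columns]
    if missing:
        raise ValueError(f"object table {path} lacks mandatory columns: {missing}")
    extra = [c for c in obj.columns if c not in OBJECT_COLUMNS]
    if extra:
        log.warning("ignoring unknown object columns: %s", extra)
        obj = obj[OBJECT_COLUMNS].copy()
    bad = obj[(obj["ellipse_major_um"] <= 0) | (obj["ellipse_minor_um"] <= 0)]
    if len(bad):
        raise ValueError(
            "non-positive ellipse axes for objects: "
            + ", ".join(map(str, bad["object_id"].head(5))))
    obj = obj.copy()
    obj["esd_um"] = compute_esd(obj["ellipse_major_um"], obj["ellipse_minor_um"])
    samples = pd.read_csv(samples_path)
    if not {"station_id", "volume_m3"} <= set(samples.columns):
        raise ValueError(f"sample table {samples_path} needs station_id, volume_m3")
    volumes = dict(zip(samples["station_id"], samples["volume_m3"].astype(float)))
    return obj, volumes


def rollup_annotate(objects: pd.DataFrame, registry: TaxonRegistry,
                    strict: bool = True) -> pd.DataFrame:
    """Expand each object into one row per ancestor group (incl. itself).

    The returned frame repeats every object once per level of its rollup
    chain, with the ancestor in the ``group`` column; summing counts at any
    node therefore accounts for all nested children exactly once.
    """
    if "esd_um" not in objects.columns:
        objects = objects.assign(
            esd_um=compute_esd(objects["ellipse_major_um"],
                               objects["ellipse_minor_um"]))
    chains: dict[str, list[str]] = {}
    for taxon in objects["taxon"].unique():
        chains[taxon] = registry.ancestors(taxon, strict=strict)
    rows = []
    for taxon, chain in chains.items():
        sub = objects[objects["taxon"] == taxon]
        for anc in chain:
            rows.append(sub.assign(group=anc))
    return pd.concat(rows, ignore_index=True)


def station_group_metrics(objects: pd.DataFrame, volumes: dict[str, float],
                          registry: TaxonRegistry | None = None,
                          min_n: int = MIN_N_INDIVIDUALS,
                          strict: bool = True) -> pd.DataFrame:
    """Per station x net x group: individual count, abundance, median ESD.

    ``abundance = count / volume`` (ind m-3); the median ESD is reported
    only when at least ``min_n`` individuals were measured.  When a
    registry is given, objects are rolled up through it first.
    """
    for st in objects["station_id"].unique():
        v = volumes.get(st)
        if v is None or v <= 0:
            raise ValueError(f"missing or non-positive volume for station {st!r}")
    if "esd_um" not in objects.columns:
        objects = objects.assign(
            esd_um=compute_esd(objects["ellipse_major_um"],
                               objects["ellipse_minor_um"]))
    ann = (rollup_annotate(objects, registry, strict=strict)
           if registry is not None else objects.assign(group=objects["taxon"]))
    grouped = ann.groupby(["station_id", "net_id", "group"], sort=True)
    out = grouped["esd_um"].agg(n_individuals="size", median_esd_um="median")
    out = out.reset_index()
    out["abundance"] = (out["n_individuals"]
                        / out["station_id"].map(volumes).astype(float))
    out.loc[out["n_individuals"] < min_n, "median_esd_um"] = np.nan
    return out[["station_id", "net_id", "group", "n_individuals",
                "abundance", "median_esd_um"]]


def retain_groups(table: pd.DataFrame, min_stations: int = MIN_STATIONS,
                  min_n: int = MIN_N_INDIVIDUALS) -> pd.DataFrame:
    """Which (group, net, metric) combinations have enough coverage to model.

    For the size-structure metric a (group, net) needs >= ``min_stations``
    stations each with >= ``min_n`` measured individuals; for the abundance
    metric it needs >= ``min_stations`` stations with the group observed.
    """
    rows = []
    for (group, net), sub in table.groupby(["group", "net_id"], sort=True):
        n_obs = int((sub["n_individuals"] > 0).sum())
        n_esd = int((sub["n_individuals"] >= min_n).sum())
        if n_obs >= min_stations:
            rows.append((group, net, "abundance", n_obs))
        if n_esd >= min_stations:
            rows.append((group, net, "median_esd", n_esd))
    return pd.DataFrame(rows, columns=["group", "net_id", "metric", "n_stations"])


def composition_by_band(table: pd.DataFrame, stations: pd.DataFrame,
                        registry: TaxonRegistry,
                        lump_below: float = 0.01) -> pd.DataFrame:
    """Relative copepod order/family composition per latitudinal band and net.

    Within each band and net, a taxon's fraction is its summed abundance
    over the band's copepod total; taxa under ``lump_below`` are pooled
    into ``other``.  Unidentified buckets are kept at order level but
    excluded from the family-level breakdown.
    """
    lat = dict(zip(stations["station_id"], np.abs(stations["latitude"])))
    orders = set(registry.children("Copepoda")) - set(UNIDENTIFIED_BUCKETS)
    families = {g for g in registry.parents
                if registry.parents[g] in orders and g not in UNIDENTIFIED_BUCKETS}
    taxa = sorted(orders | families)

    tab = table[table["group"].isin(taxa + ["Copepoda"])].copy()
    tab["abs_lat"] = tab["station_id"].map(lat)

    def band_of(a: float) -> str:
        for name, (lo, hi) in BANDS.items():
            if lo < a <= hi or (lo == 0.0 and a == 0.0):
                return name
        return "polar"

    tab["band"] = tab["abs_lat"].map(band_of)
    rows = []
    for (band, net), sub in tab.groupby(["band", "net_id"], sort=True):
        cop_total = sub.loc[sub["group"] == "Copepoda", "abundance"].sum()
        if cop_total <= 0:
            log.warning("band %s / net %s has no copepods; omitted", band, net)
            continue
        for level, members in (("order", orders), ("family", families)):
            fr = (sub[sub["group"].isin(members)]
                  .groupby("group")["abundance"].sum() / cop_total)
            # at family level, normalise within the family total so the
            # displayed fractions (plus "other") close to 1
            denom = fr.sum()
            if denom <= 0:
                continue
            fr = fr / denom
            other = float(fr[fr < lump_below].sum())
            for g, f in fr[fr >= lump_below].items():
                rows.append((band, net, level, g, float(f)))
            if other > 0:
                rows.append((band, net, level, "other", other))
    return pd.DataFrame(rows, columns=["band", "net_id", "level", "group",
                                       "fraction"])
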