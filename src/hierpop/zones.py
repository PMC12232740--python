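"""Seed-zone delineation and benchmarking.

Stand-level features from phenotypic BLUPs, geography, climate, or
SNP-predicted phenotypes; k-means zone delineation; cluster purity against a
true zoning; and a replicated benchmark comparing the data types under
different truth definitions (zones = rivers, or k-means of phenotypes).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .rng import child_rng
from .types import SampleHierarchy


def stand_features(
    values: pd.DataFrame | pd.Series,
    hierarchy: SampleHierarchy,
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-stand means of genotype-level values, column-standardized.

    ``values`` is indexed by genotype id (one column per trait/variable).
    Stands without any genotype in ``values`` are excluded.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame("value")
    stand_of = hierarchy.table.set_index("genotype")["stand"]
    frame = values.copy()
    frame["__stand"] = stand_of.reindex(frame.index)
    frame = frame.dropna(subset=["__stand"])
    feats = frame.groupby("__stand").mean()
    feats.index.name = "stand"
    if standardize:
        sd = feats.std(ddof=0)
        keep = sd > 0
        feats = (feats.loc[:, keep] - feats.loc[:, keep].mean()) / sd[keep]
    return feats


def kmeans_zones(features: pd.DataFrame, k: int, restarts: int = 50, seed: int = 0) -> pd.Series:
    """Best-of-restarts k-means partition of stands into k zones."""
    if k > len(features):
        raise ValueError(f"K={k} exceeds the number of stands ({len(features)})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed) % (2**31))
    labels = km.fit_predict(features.to_numpy(dtype=float))
    return pd.Series(labels, index=features.index, name="zone")


def cluster_purity(truth: pd.Series, recon: pd.Series) -> float:
    """Proportion of stands whose reconstructed zone's majority true zone they share.

    purity = (1/N) * sum over reconstructed zones of the largest overlap with
    any single true zone. Invariant to label permutation in either partition.
    """
    common = truth.index.intersection(recon.index)
    if len(common) == 0:
        raise ValueError("partitions share no stands")
    if len(common) != len(truth) or len(common) != len(recon):
        raise ValueError("partitions must cover the same stand set")
    t = truth.loc[common]
    r = recon.loc[common]
    total = 0
    for _, members in r.groupby(r):
        total += t.loc[members.index].value_counts().iloc[0]
    return float(total) / len(common)


def rivers_as_zones(hierarchy: SampleHierarchy) -> pd.Series:
    """The 'true' partition in which every river is one seed zone."""
    return hierarchy.river_of_stand().rename("zone")


def zone_benchmark(
    sources: dict[str, pd.DataFrame],
    hierarchy: SampleHierarchy,
    pheno_features: pd.DataFrame,
    truth_defs: tuple[str, ...] = ("rivers", "kmeans16", "kmeans3"),
    n_replicates: int = 100,
    restarts: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster-purity benchmark over data sources and truth definitions.

    ``sources`` maps a data-type name to its stand-level feature matrix;
    ``pheno_features`` is the phenotype feature matrix used both as a source
    and to define k-means truths. Truths: 'rivers' (fixed), 'kmeans16' and
    'kmeans3' (k-means of phenotypes, refit per replicate with its own seed).
    Reconstruction k-means also draw per-replicate seeds. Mean and SE over
    replicates are reported.
    """
    n_rivers = hierarchy.table["river"].nunique()
    rows = []
    for rep in range(n_replicates):
        rep_seed = int(child_rng(seed, "zone_benchmark", rep).integers(2**31))
        truths = {}
        for td in truth_defs:
            if td == "rivers":
                truths[td] = rivers_as_zones(hierarchy)
            elif td.startswith("kmeans"):
                k = int(td.replace("kmeans", ""))
                truths[td] = kmeans_zones(pheno_features, k, restarts=restarts, seed=rep_seed)
            else:
                raise ValueError(f"unknown truth definition {td!r}")
        for td, truth in truths.items():
            k = n_rivers if td == "rivers" else int(td.replace("kmeans", ""))
            for name, feats in sources.items():
                recon = kmeans_zones(feats, k, restarts=restarts, seed=rep_seed + 1)
                rows.append(
                    {
                        "replicate": rep,
                        "truth": td,
                        "source": name,
                        "purity": cluster_purity(truth, recon),
                    }
                )
    table = pd.DataFrame(rows)
    out = (
        table.groupby(["truth", "source"])["purity"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan, n="count")
        .reset_index()
    )
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.attrs["per_replicate"] = table
    return out.drop(columns="sd")
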