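"""Over-representation analysis with an assay-restricted background.

Upper-tail hypergeometric test per pathway (population = background,
successes = pathway members within the background, draws = hit set),
BH-corrected across tested pathways. Pathway collections use GMT format.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .assoc import bh_fdr


@dataclass
class PathwayCollection:
    pathways: dict  # pathway_id -> set of member ids
    source: str = ""

    def __post_init__(self):
        for pid, members in self.pathways.items():
            if not members:
                raise ValueError(f"empty pathway {pid!r}")
            self.pathways[pid] = set(map(str, members))


def read_gmt(path, source: str = "") -> PathwayCollection:
    pathways = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = set(parts[2:])
    return PathwayCollection(pathways, source=source or str(path))


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for pid, members in collection.pathways.items():
            fh.write("\t".join([pid, collection.source] + sorted(members)) + "\n")


def enrich(hits, background, pathways: PathwayCollection) -> pd.DataFrame:
    """Hypergeometric enrichment of ``hits`` against ``background``.

    P[X >= k] with population N = |background|, K = |pathway ∩ background|,
    n = |hits|; pathways with K = 0 are skipped. Hits must be a subset of
    the background.
    """
    hits = set(map(str, hits))
    background = set(map(str, background))
    stray = hits - background
    if stray:
        raise ValueError(f"{len(stray)} hit ids outside the background, "
                         f"e.g. {sorted(stray)[:3]}")
    N, n = len(background), len(hits)
    rows = []
    for pid, members in pathways.pathways.items():
        K = len(members & background)
        if K == 0:
            continue
        k = len(members & hits)
        pval = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(pathway_id=pid, k=k, K=K, n=n, N=N,
                         pval=min(pval, 1.0)))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["qval"] = bh_fdr(out["pval"])
        out = out.sort_values("pval", kind="mergesort").reset_index(drop=True)
    return out
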