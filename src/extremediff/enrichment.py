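"""Gene-set over-representation analysis with whitelist rescue.

The query gene list (genes carrying or near common differential SNVs)
is tested against each gene set with the one-sided upper-tail
hypergeometric probability (Fisher's exact test for over-representation,
raw P < alpha). Genes in significant trait-relevant sets are kept, and
genes belonging to any of the well-known whitelist pathways are rescued
regardless of significance.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from extremediff.config import PipelineConfig


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    label: str
    collection: str  # GO | KEGG | MeSH | custom
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} has no members")


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    label: str
    collection: str
    k: int  # overlap
    n: int  # query size
    K: int  # set size within background
    N: int  # background size
    p_value: float
    significant: bool


def read_gmt(path: str | Path, collection: str = "custom") -> list:
    """Read gene sets from GMT (set id, description, member genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line!r}")
            sets.append(GeneSet(parts[0], parts[1], collection, frozenset(parts[2:])))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.label, *sorted(s.members)]) + "\n")


def ora_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the members of a size-K set in a size-n draw from a size-N
    background.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N and n >= 0 and K >= 0):
        raise ValueError(f"inconsistent margins k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def _bh_adjust(pvals: Sequence[float]) -> list:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


def run_ora(
    query: Iterable[str],
    collections: Sequence[GeneSet],
    background: Iterable[str],
    config: PipelineConfig | None = None,
) -> list:
    """Test every gene set with >= 1 background member against the query.

    Results are sorted by p ascending, ties by set id. Raw p-values are
    compared with alpha by default; with config.bh_correction the BH
    adjusted values are used for the significance call.
    """
    cfg = config or PipelineConfig()
    bg = frozenset(background)
    if not bg:
        raise ValueError("background gene universe is empty")
    q = frozenset(query)
    if not q <= bg:
        raise ValueError(f"query contains genes outside the background: {sorted(q - bg)[:5]}")
    N, n = len(bg), len(q)
    tested = []
    for s in collections:
        members = s.members & bg
        if not members:
            continue
        K = len(members)
        k = len(members & q)
        tested.append((s, k, K, ora_test(k, n, K, N)))
    pvals = [p for *_x, p in tested]
    decide = _bh_adjust(pvals) if cfg.bh_correction and pvals else pvals
    results = [
        EnrichmentResult(s.set_id, s.label, s.collection, k, n, K, N, p, decide[i] < cfg.ora_alpha)
        for i, (s, k, K, p) in enumerate(tested)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results


def select_functional_genes(
    results: Sequence[EnrichmentResult],
    collections: Sequence[GeneSet],
    query: Iterable[str],
    config: PipelineConfig | None = None,
) -> dict:
    """Trait-relevant gene selection with provenance.

    Union of (a) query genes in significant sets whose label matches a
    relevance keyword (case-insensitive substring) and (b) query genes
    in any whitelist pathway set regardless of significance. Returns
    {gene: sorted list of "rule:set_id" provenance strings}.
    """
    cfg = config or PipelineConfig()
    q = frozenset(query)
    sets_by_id = {s.set_id: s for s in collections}
    keywords = [k.lower() for k in cfg.relevance_keywords]
    whitelist = [w.lower() for w in cfg.whitelist_pathways]
    if not keywords and not whitelist:
        warnings.warn("no relevance keywords and no whitelist: every significant set is kept")
    selected: dict = {}

    for r in results:
        if not r.significant:
            continue
        label = r.label.lower()
        if keywords and not any(kw in label for kw in keywords):
            continue
        for gene in sets_by_id[r.set_id].members & q:
            selected.setdefault(gene, set()).add(f"significant:{r.set_id}")

    for s in collections:
        if any(w in s.label.lower() for w in whitelist):
            for gene in s.members & q:
                selected.setdefault(gene, set()).add(f"whitelist:{s.set_id}")

    return {g: sorted(p) for g, p in selected.items()}


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["set_id", "label", "collection", "k", "n", "K", "N", "p_value", "significant"])
        for r in results:
            w.writerow(
                [r.set_id, r.label, r.collection, r.k, r.n, r.K, r.N, f"{r.p_value:.6g}", int(r.significant)]
            )


def write_selected_genes_tsv(selected: dict, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "admitted_by"])
        for gene in sorted(selected):
            w.writerow([gene, ";".join(selected[gene])])
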