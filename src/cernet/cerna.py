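"""miRNA-centric ceRNA network assembly and the negative-pair table.

Under the ceRNA hypothesis, transcripts sharing miRNA response elements
compete for a common miRNA pool; in expression data this shows up as the
miRNA anti-correlating with each of its targets while the targets correlate
positively with one another. The network is assembled per tissue from
differentially expressed features only: an edge miRNA -> ceRNA requires a
predicted binding site (cleavage or mimic mode), a sufficiently negative
miRNA-ceRNA Pearson correlation, and (optionally) at least one positively
correlated competing partner under the same miRNA. Degradome-verified edges
are flagged.

Correlation is Pearson on log2(normalized value + 1e-6) over the six
within-tissue samples; the default threshold |r| >= 0.7 is a package
default, exposed because the statistic and cutoff are a modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .degradome import CleavageEvent
from .expression import DEResult, ExpressionMatrix, LOG_PSEUDOCOUNT
from .targeting import TargetSite

__all__ = [
    "CeRNAEdge",
    "NegativePairRecord",
    "correlate",
    "negative_pairs",
    "negative_pairs_table",
    "build_network",
    "export_network",
    "import_network",
    "load_reference_negative_pairs",
    "negative_pair_marginals",
]


@dataclass
class CeRNAEdge:
    mirna_id: str
    cerna_id: str
    cerna_class: str  # mRNA | lncRNA | circRNA
    tissue: str
    r: float
    mode: str  # cleavage | mimic
    degradome_verified: bool


@dataclass
class NegativePairRecord:
    """One negative-regulation DEmiRNA-DEmRNA pair (opposite DE directions)."""

    mirna_id: str
    mirna_direction: str
    transcript_id: str
    transcript_direction: str
    tissue: str
    degradome_flag: str  # Y | N


def _tissue_columns(expr: ExpressionMatrix, tissue: str) -> list[str]:
    sub = expr.tissue_samples(tissue)
    order = sub.sort_values(["condition", "replicate"]).index
    return list(order)


def correlate(
    expr_a: ExpressionMatrix,
    feature_a: str,
    expr_b: ExpressionMatrix,
    feature_b: str,
    tissue: str,
) -> float:
    """Pearson r between two features over the six within-tissue samples.

    Computed on log2(value + pseudo-count). Returns NaN (flagged undefined)
    when either series is constant; such pairs are excluded from filtering.
    """
    cols_a = _tissue_columns(expr_a, tissue)
    cols_b = _tissue_columns(expr_b, tissue)
    meta_a = expr_a.samples.loc[cols_a, ["condition", "replicate"]]
    meta_b = expr_b.samples.loc[cols_b, ["condition", "replicate"]]
    if not (meta_a.to_numpy() == meta_b.to_numpy()).all():
        raise ValueError("sample designs do not match between matrices")
    a = np.log2(expr_a.values.loc[feature_a, cols_a].to_numpy(dtype=float) + LOG_PSEUDOCOUNT)
    b = np.log2(expr_b.values.loc[feature_b, cols_b].to_numpy(dtype=float) + LOG_PSEUDOCOUNT)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def negative_pairs(
    de_mirna: Sequence[DEResult],
    de_mrna: Sequence[DEResult],
    target_sites: Iterable[TargetSite],
    degradome_events: Iterable[CleavageEvent],
    tissue: str,
) -> list[NegativePairRecord]:
    """Negative-regulation (DE miRNA, DE mRNA) target pairs for one tissue.

    One record per predicted miRNA-mRNA target pair whose two members are
    differentially expressed in opposite directions; ``degradome_flag`` is Y
    iff a cleavage event exists for the pair.
    """
    mdir = {r.feature_id: r.direction for r in de_mirna if r.tissue == tissue}
    tdir = {r.feature_id: r.direction for r in de_mrna if r.tissue == tissue}
    verified = {(e.mirna_id, e.transcript_id) for e in degradome_events}
    records: list[NegativePairRecord] = []
    seen: set[tuple[str, str]] = set()
    for site in target_sites:
        mid, tid = site.duplex.mirna_id, site.duplex.target_id
        if (mid, tid) in seen:
            continue
        dm, dt = mdir.get(mid, "ns"), tdir.get(tid, "ns")
        if {dm, dt} != {"up", "down"}:
            continue
        seen.add((mid, tid))
        records.append(
            NegativePairRecord(
                mirna_id=mid,
                mirna_direction=dm,
                transcript_id=tid,
                transcript_direction=dt,
                tissue=tissue,
                degradome_flag="Y" if (mid, tid) in verified else "N",
            )
        )
    records.sort(key=lambda r: (r.mirna_id, r.transcript_id))
    return records


def negative_pairs_table(records: Sequence[NegativePairRecord]) -> pd.DataFrame:
    """Printable table with the published column layout."""
    df = pd.DataFrame(
        [
            (r.mirna_id, r.mirna_direction, r.transcript_id, r.transcript_direction,
             r.tissue, r.degradome_flag)
            for r in records
        ]
    )
    df.columns = ["miR_name", "up/down", "Transcript", "up/down",
                  "Tissue", "Degradome Detection"]
    return df


def build_network(
    de_results: Sequence[DEResult],
    cerna_classes: Mapping[str, str],
    target_sites: Iterable[TargetSite],
    expr_gene: ExpressionMatrix,
    expr_mirna: ExpressionMatrix,
    tissue: str,
    degradome_events: Iterable[CleavageEvent] = (),
    r_threshold: float = 0.7,
    require_pair_positivity: bool = True,
    relaxed: bool | None = None,
) -> nx.Graph:
    """Assemble the per-tissue ceRNA network from DE features.

    Nodes are DE features only. An edge miRNA-ceRNA is retained iff a
    predicted site exists, the miRNA-ceRNA correlation is <= -``r_threshold``,
    and (when ``require_pair_positivity``) at least one other retained ceRNA
    of the same miRNA correlates with it at >= +``r_threshold`` (the
    competing-pair condition, applied to a fixed point). Node attributes
    carry feature class and DE direction; edges carry r, mode and the
    degradome-verified flag. Empty DE sets give an empty network.
    """
    de_here = [r for r in de_results if r.tissue == tissue and r.direction != "ns"]
    de_mirna = {r.feature_id: r for r in de_here if r.feature_class == "mirna"}
    de_cerna = {r.feature_id: r for r in de_here if r.feature_class == "gene_like"}
    if relaxed is None:
        relaxed = any(r.relaxed for r in de_here)
    verified = {(e.mirna_id, e.transcript_id) for e in degradome_events}

    # best site per (miRNA, target); cleavage preferred over mimic
    site_mode: dict[tuple[str, str], str] = {}
    for s in target_sites:
        key = (s.duplex.mirna_id, s.duplex.target_id)
        if key not in site_mode or s.duplex.mode == "cleavage":
            site_mode[key] = s.duplex.mode

    candidates: dict[tuple[str, str], float] = {}
    for (mid, tid), mode in site_mode.items():
        if mid not in de_mirna or tid not in de_cerna:
            continue
        r = correlate(expr_mirna, mid, expr_gene, tid, tissue)
        if not np.isnan(r) and r <= -r_threshold:
            candidates[(mid, tid)] = r

    if require_pair_positivity:
        cerna_r: dict[tuple[str, str], float] = {}

        def pair_r(a: str, b: str) -> float:
            key = (min(a, b), max(a, b))
            if key not in cerna_r:
                cerna_r[key] = correlate(expr_gene, key[0], expr_gene, key[1], tissue)
            return cerna_r[key]

        while True:
            by_mirna: dict[str, list[str]] = {}
            for mid, tid in candidates:
                by_mirna.setdefault(mid, []).append(tid)
            drop = [
                (mid, tid)
                for (mid, tid) in candidates
                if not any(
                    other != tid and pair_r(tid, other) >= r_threshold
                    for other in by_mirna[mid]
                )
            ]
            if not drop:
                break
            for key in drop:
                del candidates[key]

    net = nx.Graph(tissue=tissue, r_threshold=r_threshold, relaxed=bool(relaxed))
    for (mid, tid), r in sorted(candidates.items()):
        net.add_node(mid, kind="miRNA", direction=de_mirna[mid].direction, tissue=tissue)
        net.add_node(
            tid,
            kind=cerna_classes.get(tid, "mRNA"),
            direction=de_cerna[tid].direction,
            tissue=tissue,
        )
        net.add_edge(
            mid,
            tid,
            r=float(r),
            mode=site_mode[(mid, tid)],
            degradome_verified=(mid, tid) in verified,
        )
    return net


def export_network(net: nx.Graph, path: "str | Path", format: str = "graphml") -> None:
    """Write the network as GraphML or a TSV edge list (lossless round trip
    for GraphML)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "tsv":
        rows = [
            {
                "mirna_id": u if net.nodes[u]["kind"] == "miRNA" else v,
                "cerna_id": v if net.nodes[u]["kind"] == "miRNA" else u,
                **data,
            }
            for u, v, data in net.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def import_network(path: "str | Path") -> nx.Graph:
    return nx.read_graphml(str(path))


# ---------------------------------------------------------------------------
# Bundled reference table
# ---------------------------------------------------------------------------

def load_reference_negative_pairs() -> pd.DataFrame:
    """The published sugar-beet salt-stress negative-regulation miRNA-mRNA
    pair table (leaf and root), bundled with the package."""
    path = resources.files("cernet") / "data" / "salt_stress_negative_pairs.tsv"
    with path.open() as fh:
        return pd.read_csv(fh, sep="\t")


def negative_pair_marginals(table: pd.DataFrame) -> dict[str, int]:
    """Tissue and degradome-flag marginals of a negative-pair table."""
    return {
        "n_leaf": int((table["tissue"] == "leaf").sum()),
        "n_root": int((table["tissue"] == "root").sum()),
        "n_degradome_verified": int((table["degradome_detection"] == "Y").sum()),
        "n_total": int(len(table)),
    }
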