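"""Readers and writers for the exchange formats around the pipeline.

Distance matrices use square (relaxed) PHYLIP: a count line, then one row
per strain with a tab-separated label (up to 64 characters, no whitespace)
and the full row of distances.  Partitions travel as two-column TSV
(strain_id <TAB> group).  HSP sets can be exported as TSV and imported
from BLAST tabular output (outfmt 6 with columns
qseqid sseqid qstart qend sstart send length nident bitscore).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterStats, Partition
from .ddh import TaxonomicAssignment
from .distance import DistanceMatrix
from .matching import HSP, HSPSet

__all__ = [
    "write_phylip",
    "read_phylip",
    "write_partition",
    "read_partition",
    "write_hsps",
    "read_blast_tab",
    "write_assignments",
    "write_cluster_report",
]

_MAX_LABEL = 64


def write_phylip(matrix: DistanceMatrix, path: str | Path) -> None:
    for label in matrix.labels:
        if len(label) > _MAX_LABEL or any(c.isspace() for c in label):
            raise ValueError(
                f"label {label!r} unusable in relaxed PHYLIP "
                f"(max {_MAX_LABEL} chars, no whitespace)"
            )
    with open(path, "w") as fh:
        fh.write(f"{len(matrix)}\n")
        for label, row in zip(matrix.labels, matrix.values):
            fh.write(label + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise ValueError(f"{path}: empty distance matrix file")
    n = int(tokens[0])
    expect = 1 + n * (n + 1)
    if len(tokens) != expect:
        raise ValueError(
            f"{path}: expected {expect} whitespace-separated fields for a "
            f"square matrix of {n} strains, found {len(tokens)}"
        )
    labels = []
    values = np.zeros((n, n))
    for i in range(n):
        row = tokens[1 + i * (n + 1) : 1 + (i + 1) * (n + 1)]
        labels.append(row[0])
        values[i] = [float(x) for x in row[1:]]
    return DistanceMatrix(tuple(labels), values)


def write_partition(partition: Partition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("strain_id\tgroup\n")
        for sid in sorted(partition.assignment):
            fh.write(f"{sid}\t{partition.assignment[sid]}\n")


def read_partition(path: str | Path) -> Partition:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: partition TSV needs two columns")
    sid_col, grp_col = df.columns[:2]
    groups: dict[str, list[str]] = {}
    for sid, grp in zip(df[sid_col], df[grp_col]):
        groups.setdefault(str(grp), []).append(str(sid))
    return Partition.from_clusters(groups[g] for g in sorted(groups))


def write_hsps(hspset: HSPSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "a_id\tb_id\ta_start\ta_end\tb_start\tb_end\tstrand"
            "\tlength\tidentities\tscore\n"
        )
        a_id, b_id = hspset.pair
        for h in hspset.hsps:
            fh.write(
                f"{a_id}\t{b_id}\t{h.a_start}\t{h.a_end}\t{h.b_start}"
                f"\t{h.b_end}\t{h.strand}\t{h.length}\t{h.identities}"
                f"\t{h.score}\n"
            )


def read_blast_tab(
    path: str | Path,
    pair: tuple[str, str],
    len_a: int,
    len_b: int,
) -> HSPSet:
    """Import HSPs from BLAST tabular output for one genome pair.

    Expects ``-outfmt "6 qseqid sseqid qstart qend sstart send length
    nident bitscore"`` with the query being genome A.  BLAST coordinates
    are 1-based inclusive; subject start > end marks the minus strand.
    Only ungapped-compatible rows (query span == alignment length) are
    kept, since trimming relies on exact coordinate slicing.
    """
    cols = [
        "qseqid", "sseqid", "qstart", "qend", "sstart", "send",
        "length", "nident", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    hsps = []
    for row in df.itertuples(index=False):
        a_s, a_e = int(row.qstart) - 1, int(row.qend)
        if int(row.sstart) <= int(row.send):
            strand = "+"
            b_s, b_e = int(row.sstart) - 1, int(row.send)
        else:
            strand = "-"
            b_s, b_e = int(row.send) - 1, int(row.sstart)
        if a_e - a_s != int(row.length) or b_e - b_s != int(row.length):
            continue  # gapped HSP: not representable

        ident = int(row.nident)
        length = a_e - a_s
        hsps.append(
            HSP(
                a_s, a_e, b_s, b_e, strand, ident,
                score=ident - 2 * (length - ident),
            )
        )
    return HSPSet(pair, hsps, len_a, len_b).sorted()


def write_assignments(
    assignments: Sequence[TaxonomicAssignment], path: str | Path
) -> None:
    """Classification TSV: one row per strain with the dDDH-based calls."""
    with open(path, "w") as fh:
        fh.write(
            "strain_id\tdistance\tddh\tgc_diff\tsame_species"
            "\tsame_subspecies\tgc_conflict\n"
        )
        for a in assignments:
            gc = "" if a.gc_diff_to_type is None else f"{a.gc_diff_to_type:.4f}"
            fh.write(
                f"{a.strain_id}\t{a.distance_to_type:.8f}\t{a.ddh_to_type:.6f}"
                f"\t{gc}\t{a.same_species}\t{a.same_subspecies}"
                f"\t{a.gc_conflict}\n"
            )


def write_cluster_report(
    partition: Partition, stats: ClusterStats, path: str | Path
) -> None:
    payload = {
        "params": {"T": partition.T, "F": partition.F},
        "n_clusters": partition.n_clusters,
        "clusters": partition.clusters(),
        "sizes": list(stats.sizes),
        "avg_within": list(stats.avg_within),
        "max_within": list(stats.max_within),
        "summary": stats.summary
        if stats.has_multi_member_clusters
        else {"note": "no multi-member clusters"},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
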