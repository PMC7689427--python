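"""Gene-anchored interval conversion between assemblies.

Assemblies in a pangenome share no base-level coordinate system, but every
assembly carries projections of the same reference gene models. An
interval is lifted by collecting the genes it contains in the source
assembly, locating their projections in the target, sorting them by target
position, and joining them into runs wherever the gap in the target's
chromosome-wide gene order is at most ``gap`` genes. Runs with at least
``min_run`` genes are reported; when no run is that large, only the
longest run survives (status ``longest_only``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import GeneProjection

logger = logging.getLogger(__name__)

DEFAULT_GAP = 20
DEFAULT_MIN_RUN = 10


@dataclass
class LiftResult:
    source_interval: tuple[str, int, int]
    target_assembly: str
    #: (target_chrom, target_start, target_end, n_genes), sorted, disjoint
    runs: list[tuple[str, int, int, int]] = field(default_factory=list)
    status: str = "failed"  # full | longest_only | failed

    @property
    def ok(self) -> bool:
        return self.status != "failed"

    def span(self) -> tuple[str, int, int] | None:
        """Bounding interval of all runs (single-chromosome lifts)."""
        if not self.runs:
            return None
        chrom = self.runs[0][0]
        return (chrom, min(r[1] for r in self.runs),
                max(r[2] for r in self.runs))


class ProjectionIndex:
    """Per-assembly lookup of gene projections with target gene ranks.

    Genes with multiple projections on one chromosome of an assembly are
    excluded from anchoring (their placement is ambiguous), consistent with
    the gene-window filters.
    """

    def __init__(self, projections: list[GeneProjection]):
        self._by_assembly: dict[str, dict[str, GeneProjection]] = {}
        seen_multi: dict[tuple[str, str], int] = {}
        for p in projections:
            amap = self._by_assembly.setdefault(p.assembly, {})
            key = (p.assembly, p.gene_id)
            seen_multi[key] = seen_multi.get(key, 0) + 1
            if p.gene_id in amap or p.multi_projection:
                amap[p.gene_id] = None  # ambiguous anchor
            else:
                amap[p.gene_id] = p
        for (assembly, gid), n in seen_multi.items():
            if n > 1:
                self._by_assembly[assembly][gid] = None
        # chromosome-wide gene order per assembly
        self._rank: dict[str, dict[str, int]] = {}
        for assembly, amap in self._by_assembly.items():
            by_chrom: dict[str, list[GeneProjection]] = {}
            for p in amap.values():
                if p is not None:
                    by_chrom.setdefault(p.chrom, []).append(p)
            ranks: dict[str, int] = {}
            for plist in by_chrom.values():
                plist.sort(key=lambda p: (p.start, p.end, p.gene_id))
                for rank, p in enumerate(plist, 1):
                    ranks[p.gene_id] = rank
            self._rank[assembly] = ranks

    def assemblies(self) -> list[str]:
        return list(self._by_assembly)

    def get(self, assembly: str, gene_id: str) -> GeneProjection | None:
        return self._by_assembly.get(assembly, {}).get(gene_id)

    def rank(self, assembly: str, gene_id: str) -> int | None:
        return self._rank.get(assembly, {}).get(gene_id)

    def genes_in(self, assembly: str, chrom: str, start: int,
                 end: int) -> list[GeneProjection]:
        """Unambiguous projections overlapping [start, end] on chrom."""
        out = [p for p in self._by_assembly.get(assembly, {}).values()
               if p is not None and p.chrom == chrom
               and p.start <= end and start <= p.end]
        out.sort(key=lambda p: (p.start, p.end, p.gene_id))
        return out


def lift_interval(interval: tuple[str, int, int], source: str, target: str,
                  projections, gap: int = DEFAULT_GAP,
                  min_run: int = DEFAULT_MIN_RUN) -> LiftResult:
    """Lift ``interval`` (chrom, start, end; 1-based inclusive) to ``target``.

    ``projections`` may be a list of GeneProjection covering both
    assemblies or a prebuilt ProjectionIndex. ``gap`` is the maximum number
    of intervening genes (in the target's chromosome-wide gene order)
    bridged when joining anchors into a run.
    """
    index = (projections if isinstance(projections, ProjectionIndex)
             else ProjectionIndex(projections))
    chrom, start, end = interval
    result = LiftResult(source_interval=interval, target_assembly=target)
    anchors = []
    for p in index.genes_in(source, chrom, start, end):
        tp = index.get(target, p.gene_id)
        if tp is None:
            continue
        anchors.append((tp.chrom, tp.start, tp.end,
                        index.rank(target, tp.gene_id)))
    if not anchors:
        return result
    anchors.sort(key=lambda a: (a[0], a[1], a[2]))
    runs: list[list[tuple]] = [[anchors[0]]]
    for a in anchors[1:]:
        prev = runs[-1][-1]
        same_chrom = a[0] == prev[0]
        if same_chrom and abs(a[3] - prev[3]) - 1 <= gap:
            runs[-1].append(a)
        else:
            runs.append([a])
    big = [r for r in runs if len(r) >= min_run]
    if big:
        kept, status = big, "full"
    else:
        kept, status = [max(runs, key=len)], "longest_only"
    out = []
    for r in kept:
        out.append((r[0][0], min(a[1] for a in r), max(a[2] for a in r),
                    len(r)))
    out.sort(key=lambda t: (t[0], t[1]))
    result.runs = out
    result.status = status
    return result
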