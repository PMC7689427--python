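"""Haplotype-group profiles, line assignment and marker panel design.

A haplotype group (H1..H7 on wheat chromosome 6A in the motivating
analysis) is defined by the allele vector of its exemplar cultivar over
the markers inside the minimum haplotype block (MHB) — the interval
across which no recombination between groups was observed. Genotyped
lines are assigned to the group whose profile they match over their
non-missing calls; lines matching several indistinguishable profiles get
a merged label (e.g. "H4/5/6/7"), and unseen profiles are enumerated as
novel haplotypes in order of first appearance.

Panel design picks a marker subset such that every pair of group profiles
differs at >= 3 markers (redundancy against single assay failure) while
keeping markers spread across the MHB.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix

DEFAULT_MIN_DIFF = 3
DEFAULT_MIN_CALLRATE = 0.8

#: the wheat chromosome 6A minimum haplotype block (no recombination
#: breakpoints between haplotype groups across the sequenced cultivars)
WHEAT_6A_MHB = ("chr6A", 187_000_000, 445_000_000)


def interval_length_mbp(interval: tuple[str, int, int]) -> float:
    """Span of a (chrom, start, end) interval in Mbp."""
    _, start, end = interval
    return (end - start) / 1e6


@dataclass
class HaplotypeProfile:
    """Ordered marker-allele vector defining one haplotype group (or a
    merged class of indistinguishable groups)."""

    group_id: str
    interval: tuple[str, int, int] | None
    markers: list[str]
    alleles: pd.Series = field(repr=False)

    @property
    def members(self) -> list[str]:
        return self.group_id.split("/") if "/" not in self.group_id \
            else _split_merged(self.group_id)


def _split_merged(label: str) -> list[str]:
    parts = label.split("/")
    out = [parts[0]]
    prefix = "".join(ch for ch in parts[0] if not ch.isdigit())
    for p in parts[1:]:
        out.append(p if not p.isdigit() else prefix + p)
    return out


def merge_label(group_ids: list[str]) -> str:
    """Compact merged label: ["H4","H5","H6"] -> "H4/5/6"; mixed prefixes
    fall back to joining the full ids."""
    prefixes = []
    nums = []
    for gid in group_ids:
        num = "".join(itertools.takewhile(str.isdigit, gid[::-1]))[::-1]
        prefix = gid[:len(gid) - len(num)]
        prefixes.append(prefix)
        nums.append(num)
    if len(set(prefixes)) == 1 and all(nums):
        return prefixes[0] + "/".join(nums)
    return "/".join(group_ids)


def build_group_profiles(matrix: GenotypeMatrix,
                         exemplar_lines: dict[str, object],
                         interval: tuple[str, int, int] | None = None
                         ) -> list[HaplotypeProfile]:
    """One profile per haplotype group from its exemplar line(s).

    ``exemplar_lines`` maps group id to a line id or a list of replicate
    line ids. Markers with inconsistent calls among any group's replicates
    are excluded from all profiles; an exemplar with missing calls over
    the surviving panel is an error listing the offending markers. Groups
    whose profiles coincide over the panel are merged into one
    resolvability class with a merged label.
    """
    calls = matrix.calls
    marker_ids = matrix.marker_ids
    bad_markers: set[str] = set()
    for group, lines in exemplar_lines.items():
        lines = [lines] if isinstance(lines, str) else list(lines)
        sub = calls.loc[lines, marker_ids]
        for mid in marker_ids:
            vals = sub[mid].dropna().unique()
            if len(vals) > 1:
                bad_markers.add(mid)
    panel = [m for m in marker_ids if m not in bad_markers]
    profiles: dict[str, pd.Series] = {}
    for group, lines in exemplar_lines.items():
        lines = [lines] if isinstance(lines, str) else list(lines)
        # replicate consensus: first non-missing call per marker
        vec = calls.loc[lines, panel].infer_objects(copy=False).bfill().iloc[0]
        missing = [m for m in panel if pd.isna(vec[m])]
        if missing:
            raise ValueError(
                f"exemplar for {group} has missing calls at: "
                f"{', '.join(missing)}")
        profiles[group] = vec
    # merge groups indistinguishable over the panel
    classes: list[list[str]] = []
    for group in exemplar_lines:
        for cls in classes:
            if profiles[cls[0]].equals(profiles[group]):
                cls.append(group)
                break
        else:
            classes.append([group])
    out = []
    for cls in classes:
        label = cls[0] if len(cls) == 1 else merge_label(cls)
        out.append(HaplotypeProfile(group_id=label, interval=interval,
                                    markers=panel,
                                    alleles=profiles[cls[0]][panel]))
    return out


def assign_lines(matrix: GenotypeMatrix, profiles: list[HaplotypeProfile],
                 min_callrate: float = DEFAULT_MIN_CALLRATE
                 ) -> dict[str, str]:
    """Assign every genotyped line to a haplotype group label.

    A line matches a profile when all its non-missing calls over the
    shared markers agree. Exactly one match gives that group; several give
    a merged label; none gives a novel-profile label "N1", "N2", ... keyed
    by the line's full call vector in order of first appearance. Lines
    with call rate below ``min_callrate`` over the panel are "unassigned".
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    panel = [m for m in profiles[0].markers if m in matrix.calls.columns]
    novel: dict[tuple, str] = {}
    result: dict[str, str] = {}
    for line in matrix.lines:
        calls = matrix.calls.loc[line, panel]
        observed = calls.dropna()
        if len(panel) == 0 or len(observed) / len(panel) < min_callrate:
            result[line] = "unassigned"
            continue
        matches = []
        for prof in profiles:
            ref = prof.alleles[observed.index]
            if (ref.astype(str) == observed.astype(str)).all():
                matches.append(prof.group_id)
        if len(matches) == 1:
            result[line] = matches[0]
        elif matches:
            result[line] = merge_label(
                [g for m in matches for g in _split_merged(m)])
        else:
            key = tuple(calls.fillna("NA").astype(str))
            if key not in novel:
                novel[key] = f"N{len(novel) + 1}"
            result[line] = novel[key]
    return result


@dataclass
class PanelDesign:
    """Outcome of marker panel selection."""

    markers: list[str]
    positions: list[int]
    diff_matrix: pd.DataFrame = field(repr=False)
    min_pairwise_diff: int = 0
    max_gap_bp: int = 0


def _pairwise_diffs(profiles: pd.DataFrame, markers: list[str]) -> pd.DataFrame:
    groups = list(profiles.index)
    mat = pd.DataFrame(0, index=groups, columns=groups)
    sub = profiles[markers].astype(str)
    for a, b in itertools.combinations(groups, 2):
        d = int((sub.loc[a] != sub.loc[b]).sum())
        mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def _max_gap(positions: list[int], span: tuple[int, int]) -> int:
    lo, hi = span
    pts = sorted(positions)
    edges = [lo] + pts + [hi]
    return max(b - a for a, b in zip(edges, edges[1:]))


def design_panel(candidates: GenotypeMatrix, min_diff: int = DEFAULT_MIN_DIFF,
                 target_even: bool = True) -> PanelDesign:
    """Greedy marker selection for a haplotype-informed panel.

    ``candidates`` rows are group profiles (one line per group, complete
    calls). Markers are added one at a time, each maximising the minimum
    pairwise Hamming distance between group profiles over the selected
    set; ties go to the marker that most reduces the largest positional
    gap (when ``target_even``), then to candidate order. Selection stops
    once every pair differs at >= min_diff markers. If even the full
    candidate set leaves some pair short, the pair is named in the error.
    """
    profiles = candidates.calls
    if profiles.isna().any().any():
        raise ValueError("candidate profiles must be complete")
    all_markers = candidates.marker_ids
    pos = {m[0]: m[2] for m in candidates.markers}
    full = _pairwise_diffs(profiles, all_markers)
    groups = list(profiles.index)
    for a, b in itertools.combinations(groups, 2):
        if full.loc[a, b] < min_diff:
            raise ValueError(
                f"infeasible: groups {a} and {b} differ at only "
                f"{full.loc[a, b]} candidate markers (< {min_diff})")
    span = (min(pos.values()), max(pos.values()))
    selected: list[str] = []
    str_profiles = profiles.astype(str)
    # per-marker boolean difference vectors per pair, for fast min-dist
    pairs = list(itertools.combinations(groups, 2))
    diff_by_marker = {
        m: {p: str_profiles.loc[p[0], m] != str_profiles.loc[p[1], m]
            for p in pairs} for m in all_markers}
    dist = {p: 0 for p in pairs}
    while min(dist.values(), default=min_diff) < min_diff:
        best = None
        for m in all_markers:
            if m in selected:
                continue
            new_min = min(min(dist[p] + diff_by_marker[m][p], min_diff)
                          for p in pairs)
            gap = _max_gap([pos[x] for x in selected + [m]], span) \
                if target_even else 0
            key = (-new_min, gap)
            if best is None or key < best[0]:
                best = (key, m)
        m = best[1]
        selected.append(m)
        for p in pairs:
            dist[p] += diff_by_marker[m][p]
    diff = _pairwise_diffs(profiles, selected)
    offdiag = [diff.loc[a, b] for a, b in pairs]
    return PanelDesign(
        markers=selected, positions=[pos[m] for m in selected],
        diff_matrix=diff,
        min_pairwise_diff=int(min(offdiag)) if offdiag else 0,
        max_gap_bp=_max_gap([pos[m] for m in selected], span))


def resolution_report(profiles_by_platform: dict[str, list[HaplotypeProfile]]
                      ) -> pd.DataFrame:
    """Which haplotype groups each genotyping platform can tell apart.

    Profiles produced by build_group_profiles already carry merged labels
    for indistinguishable groups; the report tabulates, per platform, the
    partition of groups into these classes.
    """
    rows = []
    for platform, profiles in profiles_by_platform.items():
        classes = sorted(p.group_id for p in profiles)
        rows.append({"platform": platform,
                     "n_classes": len(classes),
                     "classes": "; ".join(classes)})
    return pd.DataFrame(rows)
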