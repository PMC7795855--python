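"""Degradome (PARE) tag mapping, cleavage-site validation and categories.

Degradome sequencing captures the uncapped 5' ends of RNA fragments. A
miRNA-guided cleavage leaves a 3' fragment whose 5' end coincides with the
target base paired to miRNA position 10, so a sharp tag peak at that position
evidences cleavage. Validated sites are ranked by the site's tag abundance
relative to the transcript's profile, using the standard five categories:

* 0 — abundance > 1, equal to the transcript maximum, maximum unique
* 1 — abundance > 1, equal to the maximum, maximum shared
* 2 — abundance > 1, below the maximum but above the median
* 3 — abundance > 1 and <= median
* 4 — abundance <= 1 (one read, incl. fractional multi-map weights)

The median is taken over positions carrying at least one tag. T-plot tables
(per-position abundance with cleavage sites flagged) are emitted for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .targeting import TargetSite

__all__ = [
    "DegradomeProfile",
    "CleavageEvent",
    "map_tags",
    "profiles_from_table",
    "profiles_to_table",
    "classify_category",
    "validate_sites",
    "tplot_table",
]

_PREFIX_NT = 20  # tag prefix used for exact matching


@dataclass
class DegradomeProfile:
    """Per-position tag 5'-end abundance for one transcript (1-based)."""

    transcript_id: str
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if (self.abundance < 0).any():
            raise ValueError(f"{self.transcript_id}: negative abundance")

    @property
    def total_tags(self) -> float:
        return float(self.abundance.sum())

    @property
    def max_value(self) -> float:
        return float(self.abundance.max()) if self.abundance.size else 0.0

    @property
    def median_value(self) -> float:
        """Median over positions carrying at least one (possibly fractional)
        tag; 0 when no position is covered."""
        covered = self.abundance[self.abundance > 0]
        return float(np.median(covered)) if covered.size else 0.0


@dataclass
class CleavageEvent:
    """A degradome-supported cleavage site."""

    mirna_id: str
    transcript_id: str
    position: int  # transcript base paired to miRNA nt 10
    tag_count: float
    category: int
    p_value: float  # binomial enrichment, reference only — not a filter
    site: TargetSite | None = None


def map_tags(
    tags: Sequence[tuple[str, str, int]],
    transcripts: Mapping[str, str],
) -> tuple[dict[str, DegradomeProfile], list[str]]:
    """Place degradome tag 5' ends on transcripts by exact prefix match.

    ``tags`` are (tag_id, sequence, count); ``transcripts`` maps id to RNA
    sequence. The first ``20`` nt of each tag (or the full tag if shorter) is
    matched exactly, sense strand only; a tag matching k positions across the
    transcriptome contributes count/k to each. Returns profiles plus the ids
    of unmatched tags.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    seqs = {tid: s.upper().replace("T", "U") for tid, s in transcripts.items()}
    abund = {tid: np.zeros(len(s)) for tid, s in seqs.items()}
    unmatched: list[str] = []
    for tag_id, seq, count in tags:
        prefix = seq.upper().replace("T", "U")[:_PREFIX_NT]
        if len(prefix) < 15:
            unmatched.append(tag_id)
            continue
        hits: list[tuple[str, int]] = []
        for tid in sorted(seqs):
            s = seqs[tid]
            i = s.find(prefix)
            while i >= 0:
                hits.append((tid, i))
                i = s.find(prefix, i + 1)
        if not hits:
            unmatched.append(tag_id)
            continue
        w = count / len(hits)
        for tid, i in hits:
            abund[tid][i] += w
    profiles = {tid: DegradomeProfile(tid, a) for tid, a in abund.items()}
    return profiles, unmatched


def profiles_from_table(
    table: pd.DataFrame, transcript_lengths: Mapping[str, int]
) -> dict[str, DegradomeProfile]:
    """Build profiles from a pre-summarized (transcript_id, position, count)
    table; positions are 1-based."""
    profiles = {
        tid: DegradomeProfile(tid, np.zeros(length))
        for tid, length in transcript_lengths.items()
    }
    for row in table.itertuples():
        profiles[row.transcript_id].abundance[int(row.position) - 1] += row.count
    return profiles


def profiles_to_table(profiles: Mapping[str, DegradomeProfile]) -> pd.DataFrame:
    rows = []
    for tid in sorted(profiles):
        a = profiles[tid].abundance
        for pos in np.nonzero(a)[0]:
            rows.append((tid, int(pos) + 1, float(a[pos])))
    return pd.DataFrame(rows, columns=["transcript_id", "position", "count"])


def classify_category(profile: DegradomeProfile, position: int) -> int:
    """Category 0-4 of the tag abundance at ``position`` (1-based)."""
    a = profile.abundance
    if position < 1 or position > a.size:
        raise ValueError(f"position {position} outside transcript {profile.transcript_id}")
    count = a[position - 1]
    if count <= 0:
        raise ValueError(
            f"no degradome tags at {profile.transcript_id}:{position}; not an event"
        )
    if count <= 1:
        return 4
    mx = profile.max_value
    if count == mx:
        return 0 if (a == mx).sum() == 1 else 1
    return 2 if count > profile.median_value else 3


def validate_sites(
    sites: Iterable[TargetSite],
    profiles: Mapping[str, DegradomeProfile],
) -> list[CleavageEvent]:
    """Turn predicted cleavage sites with degradome support into events.

    A site becomes an event iff the profile abundance at its predicted
    cleavage position is > 0. The attached binomial p-value (chance of >=
    the observed count at one position under a uniform null) is reference
    only, never a screening filter.
    """
    events: list[CleavageEvent] = []
    for site in sites:
        if site.duplex.mode != "cleavage" or site.cleavage_position is None:
            raise ValueError("validate_sites requires cleavage-mode sites")
        tid = site.duplex.target_id
        if tid not in profiles:
            raise ValueError(f"site references unknown transcript {tid!r}")
        profile = profiles[tid]
        pos = site.cleavage_position
        count = profile.abundance[pos - 1]
        if count <= 0:
            continue
        n = int(round(profile.total_tags))
        p_uniform = 1.0 / profile.abundance.size
        p_value = float(binom.sf(ceil(count) - 1, n, p_uniform)) if n > 0 else 1.0
        events.append(
            CleavageEvent(
                mirna_id=site.duplex.mirna_id,
                transcript_id=tid,
                position=pos,
                tag_count=float(count),
                category=classify_category(profile, pos),
                p_value=p_value,
                site=site,
            )
        )
    return events


def tplot_table(
    profile: DegradomeProfile, events: Iterable[CleavageEvent]
) -> pd.DataFrame:
    """Dense per-position table (position, abundance, is_cleavage_site) for
    T-plot rendering; one row per transcript position."""
    flagged = {
        e.position for e in events if e.transcript_id == profile.transcript_id
    }
    n = profile.abundance.size
    return pd.DataFrame(
        {
            "position": np.arange(1, n + 1),
            "abundance": profile.abundance,
            "is_cleavage_site": [p in flagged for p in range(1, n + 1)],
        }
    )
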