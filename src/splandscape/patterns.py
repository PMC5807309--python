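"""Binning structure-profiling reads into modification patterns.

A *pattern* is the modification signature of a single read.  In truncation
mode (SHAPE-Seq-style) the reverse transcriptase stops at the first modified
or naturally-terminating site, so a pattern is one stop index ``p`` in
``1..L`` (internal 3'->5' numbering) or the complete-read marker ``p = L+1``.
In mutation mode (MaP-style) the enzyme reads through modified sites leaving
mutations, so a pattern is the (possibly empty) set of mutated informative
sites; ``2^K`` patterns are theoretically observable over K informative
sites, but achievable modification rates keep the observed set far smaller.

Pattern counts are converted to frequencies, which form the observation
vector ``y`` of the linear model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRUNCATION = "truncation"
MUTATION = "mutation"


class PatternError(ValueError):
    pass


@dataclass(frozen=True)
class ReadPattern:
    """One modification pattern.

    ``sites`` holds internal (3'->5') indices: a single stop index for
    truncation mode (``L+1`` marks a complete read), or the sorted set of
    mutated sites for mutation mode (empty tuple = unmodified read).
    """

    mode: str
    sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.mode == TRUNCATION and len(self.sites) != 1:
            raise PatternError("truncation pattern needs exactly one stop index")
        object.__setattr__(self, "sites", tuple(sorted(self.sites)))

    @property
    def stop(self) -> int:
        if self.mode != TRUNCATION:
            raise PatternError("stop is only defined for truncation patterns")
        return self.sites[0]


@dataclass
class PatternCounts:
    """Observed patterns with read counts for one sample.

    ``frequencies()`` yields the observation vector y, summing to 1 exactly
    over the included patterns.
    """

    mode: str
    L: int
    counts: dict[ReadPattern, int] = field(default_factory=dict)
    informative_sites: tuple[int, ...] | None = None

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def patterns(self) -> list[ReadPattern]:
        return list(self.counts)

    def frequencies(self) -> tuple[list[ReadPattern], np.ndarray]:
        pats = self.patterns()
        n = self.total_reads
        if n == 0:
            raise PatternError("no reads")
        y = np.array([self.counts[p] for p in pats], dtype=float) / n
        return pats, y


def bin_truncation(read_stops: Iterable[int], L: int) -> PatternCounts:
    """Count reads by stop index (internal 1..L, complete read = L+1)."""
    counts: dict[ReadPattern, int] = {}
    n = 0
    for p in read_stops:
        if not (1 <= p <= L + 1):
            raise PatternError(f"stop index {p} outside 1..{L + 1}")
        pat = ReadPattern(TRUNCATION, (p,))
        counts[pat] = counts.get(pat, 0) + 1
        n += 1
    if n == 0:
        raise PatternError("no reads to bin")
    return PatternCounts(mode=TRUNCATION, L=L, counts=counts)


def bin_mutation(
    read_mutation_sets: Iterable[Iterable[int]],
    informative_sites: Sequence[int],
    L: int,
) -> PatternCounts:
    """Count reads by their set of mutated informative sites.

    A mutation outside the informative set signals a mis-specified chemistry
    and raises; the empty (no-mutation) pattern is counted like any other.
    """
    info = frozenset(informative_sites)
    counts: dict[ReadPattern, int] = {}
    n = 0
    for sites in read_mutation_sets:
        sites = frozenset(sites)
        bad = sites - info
        if bad:
            raise PatternError(
                f"mutated site(s) {sorted(bad)} outside the informative set"
            )
        pat = ReadPattern(MUTATION, tuple(sites))
        counts[pat] = counts.get(pat, 0) + 1
        n += 1
    if n == 0:
        raise PatternError("no reads to bin")
    return PatternCounts(
        mode=MUTATION, L=L, counts=counts,
        informative_sites=tuple(sorted(informative_sites)),
    )


def project_mutation_to_truncation(pc: PatternCounts) -> PatternCounts:
    """Project mutation patterns onto truncation-style singleton patterns.

    Each read maps to its minimum internal site index — the modification
    closest to the 3' priming site, i.e. the one a truncation protocol would
    have detected; unmodified reads map to the complete-read marker.  Total
    read count is conserved; the projection is deterministic and irreversible.
    """
    if pc.mode != MUTATION:
        raise PatternError("projection applies to mutation-mode counts")
    counts: dict[ReadPattern, int] = {}
    for pat, c in pc.counts.items():
        stop = min(pat.sites) if pat.sites else pc.L + 1
        tpat = ReadPattern(TRUNCATION, (stop,))
        counts[tpat] = counts.get(tpat, 0) + c
    return PatternCounts(mode=TRUNCATION, L=pc.L, counts=counts)


@dataclass
class CountProfile:
    """Per-site event counts and local coverages for one sample.

    ``events[l-1]`` is the number of truncations/mutations at internal site l
    (X_l treated, Y_l control); ``coverage[l-1]`` is the local coverage (C_l):
    in truncation mode the number of reads that stop at or read through l,
    in mutation mode the number of reads overlapping l (all reads, under the
    full-overlap filtering this package supports).
    """

    mode: str
    events: np.ndarray
    coverage: np.ndarray
    sample: str = "treated"

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.events.shape != self.coverage.shape:
            raise PatternError("events/coverage length mismatch")
        if np.any(self.events > self.coverage):
            raise PatternError("event count exceeds local coverage")
        if np.any(self.events < 0):
            raise PatternError("negative event count")

    @property
    def L(self) -> int:
        return len(self.events)


def site_counts(pc: PatternCounts) -> CountProfile:
    """Collapse pattern counts to per-site events and local coverages."""
    L = pc.L
    X = np.zeros(L, dtype=np.int64)
    C = np.zeros(L, dtype=np.int64)
    if pc.mode == TRUNCATION:
        for pat, c in pc.counts.items():
            p = pat.stop
            if p <= L:
                X[p - 1] += c
            # a read stopping at p covers sites 1..p (it stopped AT p);
            # a complete read covers every site
            C[: min(p, L)] += c
    else:
        n = pc.total_reads
        C[:] = n
        for pat, c in pc.counts.items():
            for s in pat.sites:
                X[s - 1] += c
    return CountProfile(mode=pc.mode, events=X, coverage=C, sample="treated")


def mean_modifications_per_read(pc: PatternCounts) -> float:
    """Average number of detected modifications per read.

    For mutation data this is the mean mutation-count over reads; for
    truncation data every non-complete read carries one detection.
    """
    n = pc.total_reads
    if pc.mode == MUTATION:
        total = sum(len(pat.sites) * c for pat, c in pc.counts.items())
    else:
        total = sum(c for pat, c in pc.counts.items() if pat.stop <= pc.L)
    return total / n


# ---------------------------------------------------------------------------
# TSV I/O (display 5'->3' coordinates at the boundary)
# ---------------------------------------------------------------------------

def _pattern_to_label(pat: ReadPattern, L: int) -> str:
    if pat.mode == TRUNCATION:
        return "full" if pat.stop == L + 1 else str(L + 1 - pat.stop)
    if not pat.sites:
        return "none"
    return ",".join(str(L + 1 - s) for s in sorted(pat.sites, reverse=True))


def _label_to_pattern(label: str, mode: str, L: int) -> ReadPattern:
    label = str(label).strip()
    if mode == TRUNCATION:
        stop = L + 1 if label == "full" else L + 1 - int(label)
        return ReadPattern(TRUNCATION, (stop,))
    if label in ("none", ""):
        return ReadPattern(MUTATION, ())
    return ReadPattern(MUTATION, tuple(L + 1 - int(x) for x in label.split(",")))


def write_pattern_tsv(pc: PatternCounts, path: str | Path) -> None:
    """Write patterns as a two-column TSV (pattern, count).

    Pattern labels use 1-based 5'->3' site indices ("full" = complete read,
    "none" = unmodified mutation-mode read); round-trips bit-exactly.
    """
    rows = sorted(
        ((_pattern_to_label(p, pc.L), c) for p, c in pc.counts.items()),
        key=lambda r: r[0],
    )
    df = pd.DataFrame(rows, columns=["pattern", "count"])
    with open(path, "w") as fh:
        fh.write(f"# mode={pc.mode}\tL={pc.L}\n")
        if pc.informative_sites is not None:
            disp = ",".join(str(pc.L + 1 - s) for s in sorted(pc.informative_sites, reverse=True))
            fh.write(f"# informative_sites={disp}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_pattern_tsv(path: str | Path) -> PatternCounts:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for ln in lines:
        if not ln.startswith("#"):
            break
        body_start += 1
        for tok in ln[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    mode = meta["mode"]
    L = int(meta["L"])
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype={"pattern": str, "count": np.int64})
    counts = {
        _label_to_pattern(row.pattern, mode, L): int(row.count)
        for row in df.itertuples()
    }
    info = None
    if "informative_sites" in meta:
        info = tuple(sorted(L + 1 - int(x) for x in meta["informative_sites"].split(",")))
    return PatternCounts(mode=mode, L=L, counts=counts, informative_sites=info)


def write_count_profile_tsv(cp: CountProfile, path: str | Path) -> None:
    """Write a per-site (site, events, coverage) TSV in 5'->3' indices."""
    L = cp.L
    df = pd.DataFrame(
        {
            "site": np.arange(1, L + 1),
            "events": cp.events[::-1],
            "coverage": cp.coverage[::-1],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# mode={cp.mode}\tsample={cp.sample}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_count_profile_tsv(path: str | Path) -> CountProfile:
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    df = pd.read_csv(Path(path), sep="\t", comment="#")
    df = df.sort_values("site")
    return CountProfile(
        mode=meta.get("mode", TRUNCATION),
        events=df["events"].to_numpy()[::-1].copy(),
        coverage=df["coverage"].to_numpy()[::-1].copy(),
        sample=meta.get("sample", "treated"),
    )
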