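"""Candidate RNA structures as binary per-site susceptibility states.

A structure is reduced to what a chemical probe can see: each nucleotide is
either *constrained* (base-paired, or engaged in a tertiary/ligand contact that
blocks modification) or *unconstrained* (susceptible to modification).
Pseudoknots and non-nested interactions are first-class citizens — they simply
contribute constrained sites like any helix.

Coordinate convention
---------------------
Internally, sites are numbered ``1..L`` from the 3' end toward the 5' end,
because the reverse transcriptase in truncation-detection protocols initiates
at a 3' priming site and the generative read model indexes sites in the order
the enzyme visits them.  All file formats and display accessors use the
conventional 5'->3' order; the conversion ``internal = L + 1 - display``
happens exactly once, at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Bracket alphabets, in nesting-layer order.  Layer 0 is the ordinary
#: secondary structure; higher layers encode pseudoknots of increasing order.
BRACKET_PAIRS: list[tuple[str, str]] = (
    [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
    + [(chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)]
)
_OPEN = {o: i for i, (o, _) in enumerate(BRACKET_PAIRS)}
_CLOSE = {c: i for i, (_, c) in enumerate(BRACKET_PAIRS)}
UNPAIRED_CHARS = frozenset(".-_,:")

CONSTRAINED = 1
UNCONSTRAINED = 0


class StructureError(ValueError):
    """Malformed structure input (unbalanced brackets, length mismatch...)."""


def display_to_internal(d: int, L: int) -> int:
    """Convert a 1-based 5'->3' site index to internal 3'->5' numbering."""
    return L + 1 - d


internal_to_display = display_to_internal  # the map is an involution


@dataclass(frozen=True)
class Structure:
    """One candidate fold as a pair list plus a binary state vector.

    Attributes
    ----------
    id : str
        Identifier, unique within a candidate set.
    sequence : str
        RNA sequence, written 5'->3' as in the source file.
    pairs : frozenset of (int, int)
        Base pairs in internal coordinates, each with ``i < j``.
    state : numpy.ndarray
        Length-L uint8 vector in internal order; 1 = constrained.  A superset
        of the paired sites: extra constrained sites encode tertiary/ligand
        contacts.
    source : str
        Provenance tag: ``sampled`` | ``spiked`` | ``manual``.
    energy : float or None
        Optional free energy in kcal/mol.
    """

    id: str
    sequence: str
    pairs: frozenset = field(default_factory=frozenset)
    state: np.ndarray = None  # type: ignore[assignment]
    source: str = "manual"
    energy: float | None = None

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if self.state is None:
            st = np.zeros(L, dtype=np.uint8)
            for i, j in self.pairs:
                st[i - 1] = st[j - 1] = CONSTRAINED
            object.__setattr__(self, "state", st)
        else:
            object.__setattr__(
                self, "state", np.asarray(self.state, dtype=np.uint8)
            )
        if len(self.state) != L:
            raise StructureError(
                f"structure {self.id!r}: state length {len(self.state)} != "
                f"sequence length {L}"
            )
        seen: set[int] = set()
        for i, j in self.pairs:
            if i == j:
                raise StructureError(f"structure {self.id!r}: self-pair ({i},{j})")
            if not (1 <= i < j <= L):
                raise StructureError(f"structure {self.id!r}: pair ({i},{j}) out of range")
            if i in seen or j in seen:
                raise StructureError(f"structure {self.id!r}: site in more than one pair")
            seen.update((i, j))
            if not (self.state[i - 1] and self.state[j - 1]):
                raise StructureError(
                    f"structure {self.id!r}: paired site not marked constrained"
                )

    # -- basic queries ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def constrained_sites(self) -> np.ndarray:
        """Internal indices (1-based) of constrained sites."""
        return np.flatnonzero(self.state == CONSTRAINED) + 1

    def unconstrained_sites(self) -> np.ndarray:
        return np.flatnonzero(self.state == UNCONSTRAINED) + 1

    # -- display-order accessors ------------------------------------------

    @property
    def state_display(self) -> np.ndarray:
        """State vector in 5'->3' order."""
        return self.state[::-1].copy()

    @property
    def pairs_display(self) -> frozenset:
        L = len(self)
        return frozenset(
            tuple(sorted((L + 1 - i, L + 1 - j))) for i, j in self.pairs
        )

    def to_dotbracket(self) -> str:
        """Render the pair set as a 5'->3' dot-bracket string.

        Pairs are assigned to bracket layers greedily so that crossing pairs
        (pseudoknots) land in distinct alphabets.  Constrained-but-unpaired
        sites render as '.'; they survive round-trips only through the
        ``constrain=`` annotation written by :func:`write_vienna`.
        """
        L = len(self)
        chars = ["."] * L
        layers: list[list[tuple[int, int]]] = []
        for i, j in sorted(self.pairs_display):
            for layer in layers:
                if all(not (a < i < b < j or i < a < j < b) for a, b in layer):
                    layer.append((i, j))
                    break
            else:
                layers.append([(i, j)])
        for depth, layer in enumerate(layers):
            if depth >= len(BRACKET_PAIRS):
                raise StructureError("pseudoknot order exceeds bracket alphabet")
            o, c = BRACKET_PAIRS[depth]
            for i, j in layer:
                chars[i - 1], chars[j - 1] = o, c
        return "".join(chars)

    def extra_constraints_display(self) -> list[int]:
        """Constrained sites that are not base-paired, in 5'->3' indices."""
        paired = {s for p in self.pairs for s in p}
        L = len(self)
        return sorted(
            L + 1 - i for i in self.constrained_sites() if i not in paired
        )


def parse_dotbracket(
    text: str,
    sequence: str,
    *,
    id: str = "s",
    source: str = "manual",
    energy: float | None = None,
    extra_constraints: Iterable[int] = (),
) -> Structure:
    """Parse one dot-bracket line (5'->3') into a :class:`Structure`.

    Parameters
    ----------
    text : str
        Dot-bracket string over the alphabet ``() [] {} <> Aa..Zz`` plus
        unpaired markers ``. - _ , :``.  Independent stacks per alphabet
        recover pseudoknots.
    sequence : str
        RNA sequence of the same length, 5'->3'.
    extra_constraints : iterable of int
        Additional constrained sites (ligand contacts, tertiary interactions),
        as 1-based 5'->3' indices.

    Raises
    ------
    StructureError
        On unbalanced brackets (naming the bracket class) or length mismatch.
    """
    L = len(sequence)
    if len(text) != L:
        raise StructureError(
            f"structure {id!r}: dot-bracket length {len(text)} != sequence length {L}"
        )
    stacks: dict[int, list[int]] = {}
    pairs_disp: list[tuple[int, int]] = []
    for pos, ch in enumerate(text, start=1):
        if ch in UNPAIRED_CHARS:
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN[ch], []).append(pos)
        elif ch in _CLOSE:
            layer = _CLOSE[ch]
            stack = stacks.get(layer, [])
            if not stack:
                o, c = BRACKET_PAIRS[layer]
                raise StructureError(
                    f"structure {id!r}: unmatched {c!r} (bracket class {o}{c}) "
                    f"at position {pos}"
                )
            pairs_disp.append((stack.pop(), pos))
        else:
            raise StructureError(f"structure {id!r}: unknown character {ch!r}")
    for layer, stack in stacks.items():
        if stack:
            o, c = BRACKET_PAIRS[layer]
            raise StructureError(
                f"structure {id!r}: {len(stack)} unmatched {o!r} "
                f"(bracket class {o}{c})"
            )
    pairs = frozenset(
        tuple(sorted((L + 1 - i, L + 1 - j))) for i, j in pairs_disp
    )
    st = np.zeros(L, dtype=np.uint8)
    for i, j in pairs:
        st[i - 1] = st[j - 1] = CONSTRAINED
    for d in extra_constraints:
        if not (1 <= d <= L):
            raise StructureError(f"structure {id!r}: constraint site {d} out of range")
        st[display_to_internal(d, L) - 1] = CONSTRAINED
    return Structure(
        id=id, sequence=sequence, pairs=pairs, state=st, source=source, energy=energy
    )


def informative_sites_for(sequence: str, chemistry: str) -> tuple[int, ...]:
    """Internal site indices assayable by a probing chemistry.

    SHAPE reports on every nucleotide; DMS only on adenines and cytosines.
    """
    L = len(sequence)
    chem = chemistry.upper()
    if chem == "SHAPE":
        return tuple(range(1, L + 1))
    if chem == "DMS":
        return tuple(
            sorted(
                display_to_internal(d, L)
                for d, base in enumerate(sequence.upper(), start=1)
                if base in "AC"
            )
        )
    raise ValueError(f"unknown chemistry {chemistry!r} (expected SHAPE or DMS)")


@dataclass
class CandidateSet:
    """An ordered set of candidate structures over one sequence.

    ``region`` (internal, inclusive) and ``informative_sites`` together define
    the sites over which two candidates are considered distinguishable by the
    data; deduplication identity is judged over their intersection.
    """

    structures: list[Structure]
    region: tuple[int, int] | None = None
    informative_sites: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.structures:
            raise StructureError("candidate set is empty")
        seqs = {s.sequence for s in self.structures}
        if len(seqs) > 1:
            raise StructureError("candidate structures do not share one sequence")
        if self.informative_sites is not None:
            self.informative_sites = tuple(sorted(self.informative_sites))

    @property
    def sequence(self) -> str:
        return self.structures[0].sequence

    @property
    def L(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)

    def identity_sites(self) -> np.ndarray:
        """Internal indices over which structure identity is judged."""
        sites = np.arange(1, self.L + 1)
        if self.region is not None:
            lo, hi = self.region
            sites = sites[(sites >= lo) & (sites <= hi)]
        if self.informative_sites is not None:
            sites = sites[np.isin(sites, self.informative_sites)]
        return sites

    def _key(self, s: Structure, full: bool) -> bytes:
        if full:
            return s.state.tobytes()
        return s.state[self.identity_sites() - 1].tobytes()

    def dedup(self, *, full_sequence: bool = False) -> "CandidateSet":
        """Drop structures indistinguishable from an earlier one.

        Identity is state-equality over ``region ∩ informative_sites`` (the
        model cannot separate structures equal there); ``full_sequence=True``
        applies the stricter whole-state identity.  First occurrence wins,
        order is otherwise preserved; removals are logged.  Idempotent.
        """
        seen: set[bytes] = set()
        kept: list[Structure] = []
        removed = 0
        for s in self.structures:
            key = self._key(s, full_sequence)
            if key in seen:
                removed += 1
                continue
            seen.add(key)
            kept.append(s)
        if not kept:
            raise StructureError("candidate set empty after deduplication")
        if removed:
            logger.info("dedup removed %d duplicate structure(s)", removed)
        return replace(self, structures=kept)

    def spike_in(self, extras: Sequence[Structure]) -> "CandidateSet":
        """Append manually supplied structures (e.g. pseudoknotted folds that
        thermodynamic samplers cannot produce), tag them ``spiked``, dedup."""
        for s in extras:
            if s.sequence != self.sequence:
                raise StructureError(
                    f"spike-in {s.id!r} sequence differs from candidate set"
                )
        spiked = [replace(s, source="spiked") for s in extras]
        return replace(self, structures=self.structures + spiked).dedup()


def motif_contains(
    structure: Structure, motif: Iterable[tuple[int, int]], min_fraction: float = 1.0
) -> bool:
    """True iff ``structure`` realizes at least ``min_fraction`` of the motif's
    base pairs (internal coordinates, i<j)."""
    motif = {tuple(sorted(p)) for p in motif}
    if not motif:
        raise StructureError("empty motif")
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must be in (0, 1]")
    hits = len(structure.pairs & motif)
    return hits >= min_fraction * len(motif)


# ---------------------------------------------------------------------------
# File I/O — multi-structure dot-bracket ("vienna") documents and FASTA
# ---------------------------------------------------------------------------

def read_fasta_sequence(path: str | Path) -> str:
    """First record of a FASTA file, as an uppercase RNA string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper().replace("T", "U")


def _parse_structure_line(line: str, sequence: str, idx: int, source: str) -> Structure:
    tokens = line.split()
    db = tokens[0]
    energy: float | None = None
    extra: list[int] = []
    sid = f"s{idx}"
    for tok in tokens[1:]:
        if tok.startswith("(") and tok.endswith(")"):
            energy = float(tok[1:-1])
        elif tok.startswith("constrain="):
            extra = [int(x) for x in tok[len("constrain="):].split(",") if x]
        elif tok.startswith("id="):
            sid = tok[3:]
        else:
            raise StructureError(f"unrecognized annotation {tok!r} on structure line {idx}")
    return parse_dotbracket(
        db, sequence, id=sid, source=source, energy=energy, extra_constraints=extra
    )


def read_vienna(path: str | Path, *, source: str = "sampled") -> CandidateSet:
    """Read a multi-structure dot-bracket document.

    Format: a ``>header`` line, the sequence (5'->3'), then one structure per
    line.  A structure line may carry a trailing free energy in parentheses,
    an ``id=NAME`` tag and a ``constrain=5,12`` list of additional constrained
    sites (1-based 5'->3').
    """
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith(("#", ";"))
    ]
    if not lines:
        raise StructureError(f"{path}: empty structure document")
    if lines[0].startswith(">"):
        lines = lines[1:]
    sequence = lines[0].upper().replace("T", "U")
    structures = [
        _parse_structure_line(ln, sequence, i, source)
        for i, ln in enumerate(lines[1:], start=1)
    ]
    return CandidateSet(structures=structures)


def write_vienna(candidates: CandidateSet, path: str | Path, header: str = "candidates") -> None:
    """Write a candidate set back to the multi-structure dot-bracket format."""
    out = [f">{header}", candidates.sequence]
    for s in candidates:
        line = s.to_dotbracket()
        if s.energy is not None:
            line += f" ({s.energy:.2f})"
        extra = s.extra_constraints_display()
        if extra:
            line += " constrain=" + ",".join(map(str, extra))
        line += f" id={s.id}"
        out.append(line)
    Path(path).write_text("\n".join(out) + "\n")
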