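"""RNA secondary structure: weighted base-pair maximization and duplex geometry.

The folder maximizes the total pair weight (GC=3, AU=2, GU=1) over all
pseudoknot-free pairings with a minimum hairpin loop of 3, via the classic
O(n^3) dynamic program.  This captures hairpin topology -- which is what the
miRNA/miRNA* duplex criteria need -- without a thermodynamic model; scores are
pair-weight units, not kcal/mol.  An external thermodynamic folder can be
registered as a plug-in (see ``register_folder``) for users who want free
energies; its scores are flagged as kcal/mol.

Traceback is deterministic: position i prefers pairing over remaining
unpaired, and among equally scoring partners takes the smallest closing j.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

logger = logging.getLogger(__name__)

MIN_LOOP = 3  # unpaired bases required inside a hairpin loop

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_WEIGHTS = np.zeros((5, 5), dtype=np.int32)
_WEIGHTS[_CODE["G"], _CODE["C"]] = _WEIGHTS[_CODE["C"], _CODE["G"]] = 3
_WEIGHTS[_CODE["A"], _CODE["U"]] = _WEIGHTS[_CODE["U"], _CODE["A"]] = 2
_WEIGHTS[_CODE["G"], _CODE["U"]] = _WEIGHTS[_CODE["U"], _CODE["G"]] = 1


@dataclass
class SecondaryStructure:
    """A sequence with its pairing, dot-bracket string and score.

    ``pairs[i]`` is the partner of position i, or -1 if unpaired. ``score``
    is in pair-weight units for the built-in folder; kcal/mol only when an
    external folder plug-in produced it (``energy_model`` then names it).
    """

    seq: str
    dotbracket: str
    pairs: list[int]
    score: float
    energy_model: str = "pairweight"

    def __post_init__(self) -> None:
        validate_structure(self.dotbracket, self.pairs)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DuplexReport:
    """Geometry of a miRNA/miRNA* duplex read off a precursor structure.

    Spans are 0-based half-open precursor coordinates. ``n_mismatch`` counts
    mature bases opposite unpaired star bases (internal-loop columns), i.e.
    unpaired mature bases that are not part of an asymmetric bulge and not in
    the 2-nt 3' overhang. ``mismatch_ratio`` is all unpaired mature bases in
    the pairing region divided by the mature length.
    """

    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    n_mismatch: int
    bulges: list[tuple[str, int]]  # (side in {"mature","star"}, size)
    overhang_5p: int
    overhang_3p: int
    mismatch_ratio: float
    clipped: bool = False


def pairs_to_dotbracket(pairs: Sequence[int]) -> str:
    out = []
    for i, j in enumerate(pairs):
        if j < 0:
            out.append(".")
        elif j > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def dotbracket_to_pairs(db: str) -> list[int]:
    pairs = [-1] * len(db)
    stack: list[int] = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[i], pairs[j] = j, i
        elif ch != ".":
            raise ValueError(f"illegal dot-bracket character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' remains")
    return pairs


def validate_structure(db: str, pairs: Sequence[int]) -> None:
    """Check bracket/pair-table consistency, symmetry and loop size."""
    if len(db) != len(pairs):
        raise ValueError("dotbracket and pair table lengths differ")
    if dotbracket_to_pairs(db) != list(pairs):
        raise ValueError("dotbracket inconsistent with pair table")
    for i, j in enumerate(pairs):
        if j >= 0:
            if pairs[j] != i:
                raise ValueError(f"pair table not symmetric at {i}")
            if abs(j - i) <= MIN_LOOP:
                raise ValueError(f"hairpin loop below {MIN_LOOP} at {i}")


@njit(cache=True)
def _fill(codes, wmat, minloop):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(minloop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]
            for k in range(i + minloop + 1, j + 1):
                w = wmat[codes[i], codes[k]]
                if w > 0:
                    v = w
                    if k - 1 >= i + 1:
                        v += M[i + 1, k - 1]
                    if k + 1 <= j:
                        v += M[k + 1, j]
                    if v > best:
                        best = v
            M[i, j] = best
    return M


@njit(cache=True)
def _traceback(M, codes, wmat, minloop):  # pragma: no cover
    n = codes.shape[0]
    pairs = np.full(n, -1, dtype=np.int32)
    stack_i = np.empty(2 * n + 4, dtype=np.int32)
    stack_j = np.empty(2 * n + 4, dtype=np.int32)
    top = 0
    stack_i[top] = 0
    stack_j[top] = n - 1
    top += 1
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        while i < j and M[i, j] > 0:
            target = M[i, j]
            paired = False
            for k in range(j, i + minloop, -1):
                w = wmat[codes[i], codes[k]]
                if w > 0:
                    v = w
                    if k - 1 >= i + 1:
                        v += M[i + 1, k - 1]
                    if k + 1 <= j:
                        v += M[k + 1, j]
                    if v == target:
                        pairs[i] = k
                        pairs[k] = i
                        if k + 1 <= j:
                            stack_i[top] = k + 1
                            stack_j[top] = j
                            top += 1
                        i, j = i + 1, k - 1
                        paired = True
                        break
            if not paired:
                i += 1
    return pairs


def fold(seq: str) -> SecondaryStructure:
    """Maximum-weight non-crossing pairing of ``seq`` (RNA; N never pairs)."""
    if len(seq) < 10:
        raise ValueError(f"sequence too short to fold ({len(seq)} < 10)")
    rna = seq.upper().replace("T", "U")
    try:
        codes = np.array([_CODE[c] for c in rna], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"illegal base {exc.args[0]!r} in sequence") from None
    M = _fill(codes, _WEIGHTS, MIN_LOOP)
    pairs = [int(x) for x in _traceback(M, codes, _WEIGHTS, MIN_LOOP)]
    return SecondaryStructure(
        seq=rna,
        dotbracket=pairs_to_dotbracket(pairs),
        pairs=pairs,
        score=float(M[0, len(rna) - 1]),
    )


# ---------------------------------------------------------------------------
# folder plug-in registry
# ---------------------------------------------------------------------------

FOLDERS: dict[str, Callable[[str], SecondaryStructure]] = {"builtin": fold}


def register_folder(name: str, fn: Callable[[str], SecondaryStructure]) -> None:
    """Register an alternative folding engine (e.g. a thermodynamic one).

    The callable must accept an RNA string and return a SecondaryStructure;
    if it reports kcal/mol it should set ``energy_model`` accordingly.
    """
    FOLDERS[name] = fn


def get_folder(name: str) -> Callable[[str], SecondaryStructure]:
    try:
        return FOLDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown folder {name!r}; registered: {sorted(FOLDERS)}"
        ) from None


# ---------------------------------------------------------------------------
# duplex extraction
# ---------------------------------------------------------------------------


def extract_duplex(
    structure: SecondaryStructure, mature_span: tuple[int, int]
) -> DuplexReport | None:
    """Locate the miRNA* span and duplex diagnostics for a mature span.

    The star span follows the Dicer 2-nt 3' overhang convention: the star
    starts at the partner of the mature base 2 in from its 3' end and ends 2
    bases 3' of the partner of the mature 5' base, clipped to the precursor
    (with a logged warning). Returns None when the mature arm pairs with
    itself, spans both arms, or fewer than half its bases are paired.
    """
    a, b = mature_span
    n = len(structure.seq)
    if not (0 <= a < b <= n):
        raise ValueError(f"mature span {mature_span} outside structure 0..{n}")
    pairs = structure.pairs
    L = b - a
    partners = [(i, pairs[i]) for i in range(a, b) if pairs[i] >= 0]
    if 2 * len(partners) < L:
        return None
    if any(a <= j < b for _, j in partners):
        return None  # mature arm pairs with itself
    left = [j for _, j in partners if j < a]
    right = [j for _, j in partners if j >= b]
    if left and right:
        return None  # mature crosses the terminal loop
    # pairing region excludes the 2-nt 3' overhang of the mature
    region_end = b - 2  # half-open
    region = [(i, pairs[i]) for i in range(a, region_end) if pairs[i] >= 0]
    if not region:
        return None
    first_i, first_j = region[0]
    last_i, last_j = region[-1]
    # extrapolate the star ends across unpaired mature termini
    hi = first_j + (first_i - a) + 2
    lo = last_j - ((region_end - 1) - last_i)
    clipped = False
    if lo < 0 or hi > n - 1:
        clipped = True
        logger.warning("star span clipped at precursor edge")
        lo, hi = max(lo, 0), min(hi, n - 1)
    star_span = (lo, hi + 1)
    if not (star_span[1] <= a or star_span[0] >= b):
        return None  # star overlaps mature: degenerate hairpin
    # walk internal loops between consecutive paired mature positions
    n_mismatch = 0
    bulges: list[tuple[str, int]] = []
    # unpaired mature bases at the ends of the pairing region are mismatches
    n_mismatch += first_i - a
    n_mismatch += (region_end - 1) - last_i
    for (i1, j1), (i2, j2) in zip(region, region[1:]):
        um = i2 - i1 - 1
        us = abs(j2 - j1) - 1
        n_mismatch += min(um, us)
        if um > us:
            bulges.append(("mature", um - us))
        elif us > um:
            bulges.append(("star", us - um))
    n_unpaired = sum(1 for i in range(a, region_end) if pairs[i] < 0)
    # overhangs: bases 3' of the last pairing on each strand
    s_lo, s_hi = star_span
    mature_paired = [i for i in range(a, b) if s_lo <= pairs[i] < s_hi and pairs[i] >= 0]
    star_paired = [j for j in range(s_lo, s_hi) if a <= pairs[j] < b and pairs[j] >= 0]
    overhang_3p = (b - 1) - max(mature_paired) if mature_paired else 0
    # the star reads 5'->3' in increasing precursor coordinate on either arm,
    # so its 3' overhang sits at the high-coordinate end of the star span
    overhang_5p = (s_hi - 1) - max(star_paired) if star_paired else 0
    return DuplexReport(
        mature_span=(a, b),
        star_span=star_span,
        n_mismatch=n_mismatch,
        bulges=bulges,
        overhang_5p=overhang_5p,
        overhang_3p=overhang_3p,
        mismatch_ratio=n_unpaired / L,
        clipped=clipped,
    )


# ---------------------------------------------------------------------------
# Vienna-style three-line text records
# ---------------------------------------------------------------------------


def write_vienna(
    entries: Sequence[tuple[str, SecondaryStructure]],
) -> str:
    """Serialize (id, structure) pairs as id / sequence / dot-bracket records."""
    lines = []
    for name, st in entries:
        lines.append(f">{name}")
        lines.append(st.seq)
        lines.append(f"{st.dotbracket} ({st.score:g})")
    return "\n".join(lines) + ("\n" if lines else "")


def read_vienna(text: str) -> list[tuple[str, SecondaryStructure]]:
    out = []
    lines = [l for l in text.splitlines() if l.strip()]
    for i in range(0, len(lines), 3):
        name = lines[i].lstrip(">").strip()
        seq = lines[i + 1].strip()
        db_field = lines[i + 2].split()
        db = db_field[0]
        score = 0.0
        if len(db_field) > 1:
            score = float(db_field[1].strip("()"))
        out.append(
            (name, SecondaryStructure(seq, db, dotbracket_to_pairs(db), score))
        )
    return out
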