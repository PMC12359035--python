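"""Secondary-structure filtering of Sm-site hits.

A candidate Sm-site is kept only when structure is predicted to begin close to
the site on both sides: within 20 nt at the 3' end of the upstream window and
within 10 nt at the 5' end of the downstream window.  The two windows are
folded independently, excluding the motif itself.

The default folder is a weighted base-pair maximization (Nussinov-style)
dynamic program over non-crossing pairings with Watson-Crick and wobble pairs
(GC = 3, AU = 2, GU = 1), a minimum hairpin loop, and a post-pass that
unpairs isolated helices shorter than ``min_helix``.  The decision the
pipeline consumes is binary -- "is any base paired inside the window" -- which
this folder supports exactly and deterministically.  An external dot-bracket
provider (e.g. RNAfold output read from a sidecar file) can be substituted;
the decision depends only on the dot-bracket string.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


from smsite.smsite_scan import SmSiteHit, normalize_rna, resolve_structure

__all__ = [
    "PAIR_WEIGHTS",
    "FoldResult",
    "StructureDecision",
    "fold_rna",
    "flank_structured",
    "decide_structure",
    "apply_structure_filter",
    "read_sidecar",
    "SidecarFolder",
]

#: default pair weights (dimensionless): GC=3, AU=2, GU=1
PAIR_WEIGHTS: dict[frozenset, int] = {
    frozenset("GC"): 3,
    frozenset("AU"): 2,
    frozenset("GU"): 1,
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
UP_WINDOW = 20  # nt at the 3' end of the upstream fold
DOWN_WINDOW = 10  # nt at the 5' end of the downstream fold


def _weight_matrix(weights: dict[frozenset, int]) -> np.ndarray:
    w = np.zeros((4, 4), dtype=np.int32)
    for pair, val in weights.items():
        a, b = sorted(pair)
        w[_BASE_INDEX[a], _BASE_INDEX[b]] = val
        w[_BASE_INDEX[b], _BASE_INDEX[a]] = val
    return w


_DEFAULT_W = _weight_matrix(PAIR_WEIGHTS)


def _encode(seq: str) -> np.ndarray:
    enc = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq):
        if c not in _BASE_INDEX:
            raise ValueError(f"illegal RNA character: {c!r}")
        enc[i] = _BASE_INDEX[c]
    return enc


@njit(cache=True)
def _nussinov_fill(enc, wmat, min_loop):  # pragma: no cover - jit kernel
    n = enc.shape[0]
    W = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                w = wmat[enc[i], enc[k]]
                if w > 0:
                    cand = w
                    if k - 1 >= i + 1:
                        cand += W[i + 1, k - 1]
                    if k + 1 <= j:
                        cand += W[k + 1, j]
                    if cand > best:
                        best = cand
            W[i, j] = best
    return W


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: dot-bracket string and summed pair weight."""

    sequence: str
    dotbracket: str
    score: int

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pairs_from_dotbracket(self.dotbracket)

    @property
    def paired_positions(self) -> set[int]:
        return {i for i, c in enumerate(self.dotbracket) if c != "."}


def pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def _traceback(
    W: np.ndarray, enc: np.ndarray, wmat: np.ndarray, min_loop: int
) -> list[tuple[int, int]]:
    # Deterministic tie-break: prefer pairing i with the smallest admissible
    # partner, recursing left to right.
    pairs: list[tuple[int, int]] = []
    stack = [(0, enc.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = W[i, j]
        if target == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            w = int(wmat[enc[i], enc[k]])
            if w == 0:
                continue
            cand = w
            if k - 1 >= i + 1:
                cand += int(W[i + 1, k - 1])
            if k + 1 <= j:
                cand += int(W[k + 1, j])
            if cand == target:
                pairs.append((i, k))
                stack.append((k + 1, j))
                stack.append((i + 1, k - 1))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return sorted(pairs)


def _prune_short_helices(
    pairs: list[tuple[int, int]], min_helix: int
) -> list[tuple[int, int]]:
    """Drop isolated helices (maximal stacks of nested adjacent pairs)
    shorter than ``min_helix``."""
    if min_helix <= 1 or not pairs:
        return pairs
    kept: list[tuple[int, int]] = []
    pairset = set(pairs)
    seen: set[tuple[int, int]] = set()
    for p in pairs:
        if p in seen:
            continue
        helix = [p]
        i, j = p
        while (i + 1, j - 1) in pairset:
            i, j = i + 1, j - 1
            helix.append((i, j))
        seen.update(helix)
        if len(helix) >= min_helix:
            kept.extend(helix)
    return sorted(kept)


def fold_rna(
    seq: str,
    min_loop: int = 3,
    weights: dict[frozenset, int] | None = None,
    min_helix: int = 2,
) -> FoldResult:
    """Fold an RNA by weighted base-pair maximization.

    The dynamic program maximizes total pair weight over non-crossing
    pairings with hairpin loops of at least ``min_loop`` unpaired bases;
    isolated helices shorter than ``min_helix`` are unpaired in a post-pass
    and the score recomputed.
    """
    seq = normalize_rna(seq)
    if not 1 <= len(seq) <= 1000:
        raise ValueError(f"sequence length {len(seq)} outside [1, 1000]")
    wmat = _DEFAULT_W if weights is None else _weight_matrix(weights)
    enc = _encode(seq)
    n = len(seq)
    if n <= min_loop + 1:
        return FoldResult(seq, "." * n, 0)
    W = _nussinov_fill(enc, wmat, np.int64(min_loop))
    pairs = _traceback(W, enc, wmat, min_loop)
    pairs = _prune_short_helices(pairs, min_helix)
    db = ["."] * n
    score = 0
    for i, j in pairs:
        db[i], db[j] = "(", ")"
        score += int(wmat[enc[i], enc[j]])
    return FoldResult(seq, "".join(db), score)


@dataclass(frozen=True)
class StructureDecision:
    """Per-hit flags: structure near the site on each side; retained = both."""

    upstream_ok: bool
    downstream_ok: bool

    @property
    def retained(self) -> bool:
        return self.upstream_ok and self.downstream_ok


def flank_structured(fold: FoldResult, side: str, window: int) -> bool:
    """Is any base paired within ``window`` nt of the site-proximal end?

    For the upstream fold the site-proximal end is the 3' end (last ``window``
    positions); for the downstream fold it is the 5' end (first ``window``
    positions).  Windows longer than the fold are clipped.
    """
    n = len(fold.dotbracket)
    window = min(window, n)
    if side == "upstream":
        zone = range(n - window, n)
    elif side == "downstream":
        zone = range(window)
    else:
        raise ValueError(f"unknown side: {side!r}")
    paired = fold.paired_positions
    return any(i in paired for i in zone)


Folder = Callable[[str, str], str]
"""A folding backend: (sequence, window_id) -> dot-bracket string."""


def builtin_folder(seq: str, window_id: str = "") -> str:
    return fold_rna(seq).dotbracket


class SidecarFolder:
    """Dot-bracket provider backed by a two-column TSV (window_id, dotbracket).

    Window ids follow ``<transcript_id>:<start>:<motif>:up|down``.  Lets
    externally computed structures (e.g. RNAfold) replace the built-in folder;
    identical dot-brackets give identical decisions.
    """

    def __init__(self, table: dict[str, str]):
        self.table = table

    def __call__(self, seq: str, window_id: str) -> str:
        try:
            db = self.table[window_id]
        except KeyError:
            raise KeyError(f"window {window_id!r} missing from sidecar") from None
        if len(db) != len(seq):
            raise ValueError(
                f"sidecar dot-bracket length {len(db)} != window length "
                f"{len(seq)} for {window_id!r}"
            )
        return db


def read_sidecar(path) -> SidecarFolder:
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            window_id, db = line.split("\t")
            table[window_id] = db
    return SidecarFolder(table)


def hit_window_id(hit: SmSiteHit, side: str) -> str:
    suffix = "up" if side == "upstream" else "down"
    return f"{hit.transcript_id}:{hit.start}:{hit.motif_name}:{suffix}"


def decide_structure(
    hit: SmSiteHit,
    up_window: int = UP_WINDOW,
    down_window: int = DOWN_WINDOW,
    folder: Folder | None = None,
) -> StructureDecision:
    """Fold both flanking windows of a hit and decide retention.

    The upstream and downstream windows are folded separately (the motif
    itself is excluded).  A side with no captured sequence cannot present
    structure and fails.
    """
    folder = builtin_folder if folder is None else folder
    flags = {}
    for side, seq, window in (
        ("upstream", hit.upstream_seq, up_window),
        ("downstream", hit.downstream_seq, down_window),
    ):
        if not seq:
            flags[side] = False
            continue
        db = folder(seq, hit_window_id(hit, side))
        fold = FoldResult(seq, db, 0)
        flags[side] = flank_structured(fold, side, window)
    return StructureDecision(flags["upstream"], flags["downstream"])


def apply_structure_filter(
    hits: Sequence[SmSiteHit],
    up_window: int = UP_WINDOW,
    down_window: int = DOWN_WINDOW,
    folder: Folder | None = None,
) -> list[SmSiteHit]:
    """Resolve the structure decision on every hit (hits are not dropped;
    ``retained`` marks the ones that pass)."""
    out = []
    for h in hits:
        d = decide_structure(h, up_window, down_window, folder)
        out.append(resolve_structure(h, d.upstream_ok, d.downstream_ok))
    return out
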