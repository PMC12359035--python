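"""Degenerate motif scanning for Sm-sites and snRNP-recognition mimics.

The five Sm-site motif classes are the U1-type ``AUUUGUG``, U2-type
``AUUUUUG``, U5-type ``AUUUUUUG``, U7-type ``AUUUGUCUAG`` and the degenerate
noncanonical pattern ``AUNUKUN`` (K = G/U).  Because each canonical pattern is
contained in the noncanonical expansion, per-gene "true noncanonical" counts
subtract the canonical total from the raw noncanonical count.

Every motif occurrence captures up to 200 nt of upstream sequence and 16-50 nt
of downstream sequence for the secondary-structure filter; hits with fewer
than 16 nt available downstream are discarded outright (this is what keeps
U4atac-like RNAs, with only 8 nt past the site, out of the calls).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from smsite.annotation_io import Region, TranscriptModel, map_region

__all__ = [
    "IUPAC_RNA",
    "MotifDef",
    "MOTIFS",
    "SmSiteHit",
    "MimicHit",
    "GeneSiteSummary",
    "compile_motif",
    "scan_sm_sites",
    "summarize_gene",
    "merge_annotations",
    "scan_5ss",
    "scan_branchpoints",
    "SS5_PATTERN",
    "BPT_CONSENSUS",
    "BPT_STRINGENT",
]

# Degenerate RNA alphabet.  Subject sequences are matched after T->U
# normalization; an N in the *subject* never matches (classes contain only
# concrete letters), so ambiguous bases are rejected conservatively.
IUPAC_RNA: dict[str, str] = {
    "A": "A",
    "C": "C",
    "G": "G",
    "U": "U",
    "N": "ACGU",
    "K": "GU",
    "M": "AC",
    "R": "AG",
    "Y": "CU",
    "W": "AU",
}

UPSTREAM_WINDOW = 200  # nt captured 5' of a site
DOWNSTREAM_MAX = 50  # nt captured 3' of a site
DOWNSTREAM_MIN = 16  # minimum 3' availability; shorter tails discard the hit


@dataclass(frozen=True)
class MotifDef:
    """A named degenerate motif and its class (canonical / u7 / noncanonical)."""

    name: str
    pattern: str
    motif_class: str


MOTIFS: tuple[MotifDef, ...] = (
    MotifDef("U1", "AUUUGUG", "canonical"),
    MotifDef("U2", "AUUUUUG", "canonical"),
    MotifDef("U5", "AUUUUUUG", "canonical"),
    MotifDef("U7", "AUUUGUCUAG", "u7"),
    MotifDef("NC", "AUNUKUN", "noncanonical"),
)
MOTIF_BY_NAME = {m.name: m for m in MOTIFS}
CANONICAL_NAMES = ("U1", "U2", "U5")


def normalize_rna(seq: str) -> str:
    """Uppercase and transcribe a subject sequence into the RNA alphabet."""
    return seq.upper().replace("T", "U")


class CompiledMotif:
    """Regex-backed matcher for a degenerate RNA pattern.

    Matching is overlap-aware: every start position is reported, including
    overlapping occurrences of the same motif.
    """

    def __init__(self, pattern: str):
        if not pattern:
            raise ValueError("empty motif pattern")
        pattern = normalize_rna(pattern)
        classes = []
        for sym in pattern:
            if sym not in IUPAC_RNA:
                raise ValueError(f"illegal motif symbol: {sym!r}")
            classes.append(f"[{IUPAC_RNA[sym]}]")
        self.pattern = pattern
        self.length = len(pattern)
        self._exact = re.compile("".join(classes))
        self._scan = re.compile(f"(?={''.join(classes)})")

    def matches(self, kmer: str) -> bool:
        """True iff the k-mer is in the expansion set of the pattern."""
        return self._exact.fullmatch(normalize_rna(kmer)) is not None

    def finditer(self, seq: str) -> Iterable[int]:
        """Yield every match start in the (already normalized) subject."""
        for m in self._scan.finditer(seq):
            yield m.start()


def compile_motif(pattern: str) -> CompiledMotif:
    """Compile a degenerate RNA pattern into an overlap-aware matcher."""
    return CompiledMotif(pattern)


_COMPILED = {m.name: compile_motif(m.pattern) for m in MOTIFS}


@dataclass(frozen=True)
class SmSiteHit:
    """One motif occurrence with its captured flanking windows.

    ``start`` is the transcript coordinate of the first motif base.  The
    structure decision fields start out unset (``None``) and are resolved by
    the structure filter; ``retained`` is only meaningful afterwards.
    """

    transcript_id: str
    motif_name: str
    start: int
    site_seq: str
    upstream_seq: str
    downstream_seq: str
    region: Region = Region.NA
    upstream_ok: bool | None = None
    downstream_ok: bool | None = None

    @property
    def retained(self) -> bool | None:
        if self.upstream_ok is None or self.downstream_ok is None:
            return None
        return self.upstream_ok and self.downstream_ok

    @property
    def end(self) -> int:
        return self.start + len(self.site_seq)


def scan_sm_sites(
    transcript_id: str,
    seq: str,
    motifs: Sequence[MotifDef] = MOTIFS,
    transcript: TranscriptModel | None = None,
) -> list[SmSiteHit]:
    """Scan one transcript sequence for Sm-site motifs.

    Each motif is scanned independently, so one position can yield both a
    canonical and a noncanonical hit.  When ``transcript`` is given, each
    hit's region is assigned from its start coordinate.
    """
    seq = normalize_rna(seq)
    hits: list[SmSiteHit] = []
    for motif in motifs:
        matcher = _COMPILED.get(motif.name) or compile_motif(motif.pattern)
        mlen = matcher.length
        for start in matcher.finditer(seq):
            end = start + mlen
            if len(seq) - end < DOWNSTREAM_MIN:
                continue
            hits.append(
                SmSiteHit(
                    transcript_id=transcript_id,
                    motif_name=motif.name,
                    start=start,
                    site_seq=seq[start:end],
                    upstream_seq=seq[max(0, start - UPSTREAM_WINDOW) : start],
                    downstream_seq=seq[end : end + DOWNSTREAM_MAX],
                    region=(
                        map_region(transcript, start)
                        if transcript is not None
                        else Region.NA
                    ),
                )
            )
    hits.sort(key=lambda h: (h.start, h.motif_name))
    return hits


@dataclass
class GeneSiteSummary:
    """Per-gene Sm-site frequencies by motif class and region.

    ``canonical_total`` adds the U1/U2/U5 counts; ``nc_true`` subtracts them
    from the raw noncanonical count (every canonical site also matches the
    noncanonical pattern, so the difference is never negative).
    """

    gene_id: str
    transcript_id: str
    n_U1: int = 0
    n_U2: int = 0
    n_U5: int = 0
    n_U7: int = 0
    n_NC_raw: int = 0
    region_counts: dict = field(default_factory=dict)
    transcript_length: int = 0
    utr5_length: int = 0
    cds_length: int = 0
    utr3_length: int = 0

    @property
    def canonical_total(self) -> int:
        return self.n_U1 + self.n_U2 + self.n_U5

    @property
    def nc_true(self) -> int:
        return self.n_NC_raw - self.canonical_total


def summarize_gene(hits: Sequence[SmSiteHit], t: TranscriptModel) -> GeneSiteSummary:
    """Collapse structure-retained hits of one transcript into a summary row."""
    s = GeneSiteSummary(
        gene_id=t.gene_id,
        transcript_id=t.transcript_id,
        transcript_length=t.transcript_length,
        utr5_length=t.utr5_length,
        cds_length=t.cds_length,
        utr3_length=t.utr3_length,
    )
    for h in hits:
        if h.transcript_id != t.transcript_id:
            raise ValueError(
                f"hit on {h.transcript_id} summarized against {t.transcript_id}"
            )
        if h.retained is None:
            raise ValueError("summarize_gene requires resolved structure decisions")
        if not h.retained:
            continue
        attr = f"n_{h.motif_name}" if h.motif_name != "NC" else "n_NC_raw"
        setattr(s, attr, getattr(s, attr) + 1)
        region = map_region(t, h.start)
        mclass = MOTIF_BY_NAME[h.motif_name].motif_class
        key = (mclass, region)
        s.region_counts[key] = s.region_counts.get(key, 0) + 1
    if s.nc_true < 0:
        raise AssertionError(
            f"gene {s.gene_id}: nc_true < 0 violates motif subsumption"
        )
    return s


def _merge_key(h: SmSiteHit) -> tuple:
    return (h.transcript_id, h.motif_name, h.downstream_seq)


def merge_annotations(
    hits_a: Sequence[SmSiteHit], hits_b: Sequence[SmSiteHit]
) -> list[SmSiteHit]:
    """Reconcile hits called against two annotations of one transcript universe.

    A hit is shared when (transcript_id, motif_name, downstream_seq) occurs in
    both lists; shared hits are emitted once (from the first list), then hits
    unique to either list are appended.  The operation is idempotent,
    commutative whenever shared hits are identical in both lists, and the
    output order is deterministic.
    """
    keys_a = {_merge_key(h) for h in hits_a}
    out = list(hits_a) + [h for h in hits_b if _merge_key(h) not in keys_a]
    out.sort(key=lambda h: (h.transcript_id, h.start, h.motif_name))
    return out


@dataclass(frozen=True)
class MimicHit:
    """A 5' splice-site or branch-point mimic occurrence."""

    transcript_id: str
    kind: str
    start: int
    matched_seq: str


SS5_PATTERN = "MAGGURAGK"
BPT_CONSENSUS = "YUNAYYYY"
BPT_STRINGENT = "YMYUNACW"

_SS5 = compile_motif(SS5_PATTERN)
_SS5_CLASSES = [set(IUPAC_RNA[c]) for c in SS5_PATTERN]
# single-deletion variants of the pattern (one pattern position skipped)
_SS5_DELETIONS = tuple(
    {
        compile_motif(SS5_PATTERN[:i] + SS5_PATTERN[i + 1 :])
        for i in range(len(SS5_PATTERN))
    }
)
_BPT = {"consensus": compile_motif(BPT_CONSENSUS), "stringent": compile_motif(BPT_STRINGENT)}


def scan_5ss(transcript_id: str, seq: str, allow_bulge: bool = False) -> list[MimicHit]:
    """Scan for U1/U11 5' splice-site mimics (``MAGGURAGK``).

    With ``allow_bulge``, windows matching at exactly 8 of 9 pattern positions
    are reported as mismatch bulges, and 8-mers equal to the pattern with one
    position deleted as deletion bulges.  Each start is reported at most once
    with precedence exact > mismatch > deletion.
    """
    seq = normalize_rna(seq)
    n = len(seq)
    hits: dict[int, MimicHit] = {}
    for start in _SS5.finditer(seq):
        hits[start] = MimicHit(transcript_id, "ss5_exact", start, seq[start : start + 9])
    if allow_bulge:
        for start in range(n - 8):
            if start in hits:
                continue
            window = seq[start : start + 9]
            matched = sum(1 for c, cls in zip(window, _SS5_CLASSES) if c in cls)
            if matched == 8:
                hits[start] = MimicHit(transcript_id, "ss5_bulge_mismatch", start, window)
        for matcher in _SS5_DELETIONS:
            for start in matcher.finditer(seq):
                if start not in hits:
                    hits[start] = MimicHit(
                        transcript_id, "ss5_bulge_deletion", start, seq[start : start + 8]
                    )
    return [hits[k] for k in sorted(hits)]


def scan_branchpoints(transcript_id: str, seq: str, mode: str) -> list[MimicHit]:
    """Scan for branch-point mimics (consensus ``YUNAYYYY`` or stringent
    ``YMYUNACW``); every start is reported."""
    if mode not in _BPT:
        raise ValueError(f"unknown branch-point mode: {mode!r}")
    seq = normalize_rna(seq)
    matcher = _BPT[mode]
    return [
        MimicHit(transcript_id, f"bpt_{mode}", start, seq[start : start + matcher.length])
        for start in matcher.finditer(seq)
    ]


def resolve_structure(hit: SmSiteHit, upstream_ok: bool, downstream_ok: bool) -> SmSiteHit:
    """Return a copy of the hit with its structure decision filled in."""
    return replace(hit, upstream_ok=upstream_ok, downstream_ok=downstream_ok)
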