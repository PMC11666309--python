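"""Planted-genome fixtures and brute-force oracles.

This module generates genomes with analytically known structure: genes whose
promoter, RBS, codon string and terminator are placed explicitly, embedded in
filler that is guaranteed (by rejection sampling against an independent motif
checker, plus a post-check) to contain no promoter, no terminator and no RBS
motif on either strand.  The decoder's output on such a genome must equal the
constructed ground truth exactly.

It also provides exhaustive single-event enumeration oracles used to validate
the Monte-Carlo robustness estimators on small genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .chemistry import (
    CODON_LEN,
    GENE_HEAD_LEN,
    PROMOTER_CONSENSUS,
    PROMOTER_LEN,
    PROMOTER_MAX_MISMATCH,
    RBS_MOTIF,
    RBS_SPACER,
    STOP_CODON,
    TERMINATOR_LEN,
    W_MAX,
    promoter_expression,
)
from .decoder import LEADING, evaluate_bits
from .genome import (
    Genome,
    MutationEvent,
    MutationType,
    apply_event,
    span_length,
)

__all__ = [
    "PlantedGene",
    "PlantedGenomeSpec",
    "GroundTruth",
    "PlantedSpecError",
    "make_planted_genome",
    "make_random_genome",
    "motif_free_filler",
    "random_functional_gene",
    "cassette_self_consistent",
    "random_planted_spec",
    "gray_decode_mwh",
    "exhaustive_single_event_oracle",
    "scan_promoters",
    "scan_terminators",
    "scan_rbs_starts",
]

_CONSENSUS_BITS = tuple(int(c) for c in PROMOTER_CONSENSUS)
_RBS_BITS = tuple(int(c) for c in RBS_MOTIF)


class PlantedSpecError(ValueError):
    """The requested planted layout cannot be realized."""


# ---------------------------------------------------------------------------
# independent motif checker (pure numpy; used for rejection sampling and as
# the structural oracle in tests)
# ---------------------------------------------------------------------------


def _strand_seq(bits: np.ndarray, strand: int) -> np.ndarray:
    return bits if strand == LEADING else (1 - bits[::-1]).astype(np.uint8)


def scan_promoters(bits: np.ndarray, d_max: int = PROMOTER_MAX_MISMATCH):
    """(strand, strand-local position, mismatches) of every promoter window."""
    L = bits.size
    out = []
    cons = np.array(_CONSENSUS_BITS, dtype=np.uint8)
    for strand in (0, 1):
        seq = _strand_seq(bits, strand)
        ext = np.resize(seq, L + PROMOTER_LEN)
        d = np.zeros(L, dtype=np.int64)
        for j in range(PROMOTER_LEN):
            d += ext[j : j + L] != cons[j]
        for pos in np.nonzero(d <= d_max)[0]:
            out.append((strand, int(pos), int(d[pos])))
    return out


def scan_terminators(bits: np.ndarray):
    """(strand, strand-local position) of every stem-loop terminator."""
    L = bits.size
    out = []
    for strand in (0, 1):
        seq = _strand_seq(bits, strand)
        ext = np.resize(seq, L + TERMINATOR_LEN)
        ok = np.ones(L, dtype=bool)
        for j in range(4):
            ok &= ext[j : j + L] == 1 - ext[10 - j : 10 - j + L]
        out.extend((strand, int(p)) for p in np.nonzero(ok)[0])
    return out


def scan_rbs_starts(bits: np.ndarray):
    """(strand, strand-local position) of every RBS+spacer+START motif."""
    L = bits.size
    out = []
    motif = {i: b for i, b in enumerate(_RBS_BITS)}
    motif.update({10: 0, 11: 0, 12: 0})
    for strand in (0, 1):
        seq = _strand_seq(bits, strand)
        ext = np.resize(seq, L + GENE_HEAD_LEN)
        ok = np.ones(L, dtype=bool)
        for j, b in motif.items():
            ok &= ext[j : j + L] == b
        out.extend((strand, int(p)) for p in np.nonzero(ok)[0])
    return out


# ---------------------------------------------------------------------------
# gray-code oracle
# ---------------------------------------------------------------------------


def gray_decode_mwh(codons: list[int]) -> tuple[float, float, float]:
    """Independent table-lookup decoding of a functional codon list into
    (m, w, h), via Gray-coded binary integers.

    Codons are 3-bit values; 100/101 carry m bits, 010/011 w bits, 110/111 h
    bits; START (000) inside the frame carries nothing.
    """

    def value(bits: list[int]) -> float | None:
        if not bits:
            return None
        # Gray -> binary integer
        acc = 0
        out = 0
        for b in bits:
            acc ^= b
            out = (out << 1) | acc
        return out / (2 ** len(bits) - 1)

    m_bits = [c & 1 for c in codons if c in (0b100, 0b101)]
    w_bits = [c & 1 for c in codons if c in (0b010, 0b011)]
    h_bits = [c & 1 for c in codons if c in (0b110, 0b111)]
    vm, vw, vh = value(m_bits), value(w_bits), value(h_bits)
    m = 0.5 if vm is None else vm
    w = 0.0 if vw is None else vw * W_MAX
    h = 0.0 if vh is None else vh * 2.0 - 1.0
    return m, w, h


# ---------------------------------------------------------------------------
# planted genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedGene:
    """One gene cassette: promoter (with ``mismatches`` planted errors),
    RBS+spacer+START, a codon bit-string, STOP and a terminator."""

    codons: str                       # bit string, length multiple of 3
    strand: int = LEADING
    mismatches: int = 0
    spacer: str = "0000"
    mismatch_positions: tuple[int, ...] | None = None

    def __post_init__(self):
        if len(self.codons) % CODON_LEN or not self.codons:
            raise PlantedSpecError("codon string length must be a positive multiple of 3")
        if set(self.codons) - {"0", "1"} or set(self.spacer) - {"0", "1"}:
            raise PlantedSpecError("codons and spacer must be bit strings")
        if len(self.spacer) != RBS_SPACER:
            raise PlantedSpecError(f"spacer must be {RBS_SPACER} bp")
        if not 0 <= self.mismatches <= PROMOTER_MAX_MISMATCH + 1:
            raise PlantedSpecError("mismatch count out of range")

    @property
    def codon_values(self) -> list[int]:
        return [
            int(self.codons[i : i + 3], 2) for i in range(0, len(self.codons), 3)
        ]

    def cassette(self) -> str:
        prom = list(PROMOTER_CONSENSUS)
        pos = self.mismatch_positions or tuple(range(self.mismatches))
        if len(pos) != self.mismatches:
            raise PlantedSpecError("mismatch_positions must match mismatch count")
        for p in pos:
            prom[p] = "1" if prom[p] == "0" else "0"
        stop = format(STOP_CODON, "03b")
        terminator = "0110" + "000" + "1001"
        return (
            "".join(prom) + RBS_MOTIF + self.spacer + "000"
            + self.codons + stop + terminator
        )


@dataclass(frozen=True)
class PlantedGenomeSpec:
    """Total length plus an ordered list of gene cassettes separated by
    motif-free filler (fillers are sized evenly from the slack)."""

    length: int
    genes: tuple[PlantedGene, ...] = ()

    def __post_init__(self):
        if self.length < 1:
            raise PlantedSpecError("length must be >= 1")
        used = sum(len(g.cassette()) for g in self.genes)
        if used > self.length:
            raise PlantedSpecError(
                f"planted elements need {used} bp but only {self.length} available"
            )

    @classmethod
    def from_yaml(cls, text: str) -> "PlantedGenomeSpec":
        doc = yaml.safe_load(text)
        genes = tuple(
            PlantedGene(
                codons=g["codons"],
                strand=int(g.get("strand", 0)),
                mismatches=int(g.get("mismatches", 0)),
                spacer=g.get("spacer", "0000"),
                mismatch_positions=(
                    None
                    if g.get("mismatch_positions") is None
                    else tuple(g["mismatch_positions"])
                ),
            )
            for g in doc.get("genes", [])
        )
        return cls(length=int(doc["length"]), genes=genes)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "length": self.length,
                "genes": [
                    {
                        "codons": g.codons,
                        "strand": g.strand,
                        "mismatches": g.mismatches,
                        "spacer": g.spacer,
                        "mismatch_positions": (
                            None
                            if g.mismatch_positions is None
                            else list(g.mismatch_positions)
                        ),
                    }
                    for g in self.genes
                ],
            },
            sort_keys=False,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic annotation a decoder run must reproduce exactly."""

    promoters: tuple[tuple[int, int, int, float], ...]   # strand, pos, d, e
    rnas: tuple[tuple[int, int, int, int], ...]          # strand, start, len, term
    proteins: tuple[tuple[float, float, float, float, int, int, int], ...]
    coding_mask: np.ndarray
    planted_rbs: tuple[tuple[int, int], ...] = ()
    planted_terminators: tuple[tuple[int, int], ...] = ()

    @property
    def coding_size(self) -> int:
        return int(self.coding_mask.sum())


def _expected_truth(spec: PlantedGenomeSpec, offsets: list[int], L: int) -> GroundTruth:
    promoters = []
    rnas = []
    proteins = []
    planted_rbs = []
    planted_term = []
    mask = np.zeros(L, dtype=bool)
    for gene, off in zip(spec.genes, offsets):
        c = len(gene.cassette())
        if gene.strand == LEADING:
            ppos = off
        else:
            ppos = L - off - c
        n = len(gene.codons) // 3
        tlen = GENE_HEAD_LEN + 3 * n + 3 + TERMINATOR_LEN
        start = (ppos + PROMOTER_LEN) % L
        term = (ppos + PROMOTER_LEN + GENE_HEAD_LEN + 3 * n + 3) % L
        cds_start = (ppos + PROMOTER_LEN + GENE_HEAD_LEN - 3) % L
        cds_len = 3 * n + 6
        planted_rbs.append((gene.strand, start))
        planted_term.append((gene.strand, term))
        if gene.mismatches <= PROMOTER_MAX_MISMATCH:
            e = promoter_expression(gene.mismatches)
            promoters.append((gene.strand, ppos % L, gene.mismatches, e))
            rnas.append((gene.strand, start, tlen, term))
            m, w, h = gray_decode_mwh(gene.codon_values)
            if w != 0.0 and h != 0.0:
                proteins.append((m, w, h, e, gene.strand, cds_start, cds_len))
                s = (cds_start + np.arange(cds_len)) % L
                pos = s if gene.strand == LEADING else L - 1 - s
                mask[pos] = True
    promoters.sort(key=lambda t: (t[1], t[0]))
    return GroundTruth(
        promoters=tuple(promoters),
        rnas=tuple(rnas),
        proteins=tuple(proteins),
        coding_mask=mask,
        planted_rbs=tuple(planted_rbs),
        planted_terminators=tuple(planted_term),
    )


def _violations(
    bits: np.ndarray, truth: GroundTruth
) -> list[tuple[int, int, int, bool]]:
    """Unplanned motifs as (strand, strand-local pos, window length, hard).

    ``hard`` motifs change the decoding (extra promoter, transcript-truncating
    terminator, extra gene start inside a transcript) and must be removed
    wherever they are; soft motifs are harmless for decoding and only violate
    filler purity (they are fixed when they touch filler, ignored inside
    cassettes, e.g. the stem-loops the promoter consensus itself contains).
    """
    L = bits.size
    bad = []
    planted_prom = {(s, p) for s, p, _, _ in truth.promoters}
    for strand, pos, _ in scan_promoters(bits):
        if (strand, pos) not in planted_prom:
            bad.append((strand, pos, PROMOTER_LEN, True))
    planted_term = set(truth.planted_terminators)
    for strand, pos in scan_terminators(bits):
        if (strand, pos) in planted_term:
            continue
        truncates = any(
            s == strand and (pos - start) % L < tlen - TERMINATOR_LEN
            for s, start, tlen, _ in truth.rnas
        )
        bad.append((strand, pos, TERMINATOR_LEN, truncates))
    planted_rbs = set(truth.planted_rbs)
    for strand, pos in scan_rbs_starts(bits):
        if (strand, pos) in planted_rbs:
            continue
        in_transcript = any(
            s == strand and (pos - start) % L + GENE_HEAD_LEN <= tlen
            for s, start, tlen, _ in truth.rnas
        )
        bad.append((strand, pos, GENE_HEAD_LEN, in_transcript))
    return bad


_RC_CONSENSUS = tuple(1 - b for b in reversed(_CONSENSUS_BITS))
# gene-start head patterns on the stored strand (None = free spacer bit):
_HEAD_FWD = _RBS_BITS + (None,) * RBS_SPACER + (0, 0, 0)
_HEAD_REV = tuple(
    None if _HEAD_FWD[12 - j] is None else 1 - _HEAD_FWD[12 - j] for j in range(13)
)


def _tail_makes_motif(bits: list[int], i: int) -> bool:
    """Does any motif window *ending* at index ``i`` exist?  The terminator
    predicate is strand-symmetric and the other motifs are checked in both
    orientations, so scanning the stored strand covers the lagging strand."""
    if i >= 10:
        a = i - 10
        if all(bits[a + j] == 1 - bits[a + 10 - j] for j in range(4)):
            return True
    if i >= 12:
        a = i - 12
        for pat in (_HEAD_FWD, _HEAD_REV):
            if all(b is None or bits[a + j] == b for j, b in enumerate(pat)):
                return True
    if i >= PROMOTER_LEN - 1:
        a = i - PROMOTER_LEN + 1
        for cons in (_CONSENSUS_BITS, _RC_CONSENSUS):
            d = 0
            for j in range(PROMOTER_LEN):
                if bits[a + j] != cons[j]:
                    d += 1
                    if d > PROMOTER_MAX_MISMATCH:
                        break
            if d <= PROMOTER_MAX_MISMATCH:
                return True
    return False


def motif_free_filler(
    size: int, rng: np.random.Generator, circular: bool = False
) -> np.ndarray:
    """Random-looking filler with no promoter, terminator or gene-start motif
    on either strand, built incrementally: each appended bit is checked
    against every motif window it completes, flipped if needed, with bounded
    backtracking; a deterministic all-zero block (itself motif-free) is the
    last-resort fallback.

    With ``circular=True`` the block is also free of motifs in the windows
    that wrap around the origin, so it stands alone as a whole genome.
    """
    if size == 0:
        return np.empty(0, dtype=np.uint8)
    for _ in range(64):
        bits: list[int] = []
        steps = 0
        fallback = False
        while len(bits) < size:
            steps += 1
            if steps > 60 * size:  # pragma: no cover - vanishingly rare
                bits = [0] * size
                fallback = True
                break
            first = int(rng.integers(2))
            placed = False
            for b in (first, 1 - first):
                bits.append(b)
                if _tail_makes_motif(bits, len(bits) - 1):
                    bits.pop()
                else:
                    placed = True
                    break
            if not placed:
                del bits[-min(len(bits), 12):]
        out = np.array(bits, dtype=np.uint8)
        if not circular or fallback:
            return out
        if (
            not scan_promoters(out)
            and not scan_terminators(out)
            and not scan_rbs_starts(out)
        ):
            return out
    return np.zeros(size, dtype=np.uint8)  # pragma: no cover


def random_functional_gene(
    n_codons: int,
    rng: np.random.Generator,
    strand: int = 0,
    mismatches: int = 0,
    mismatch_positions: tuple[int, ...] | None = None,
    max_tries: int = 50,
) -> PlantedGene:
    """A gene with ``n_codons`` random functional codons whose cassette is
    self-consistent (codons are grown incrementally so that no terminator,
    gene-start or promoter window forms inside the cassette) and whose
    decoded protein is functional (non-zero w and h)."""
    for _ in range(max_tries):
        prefix = [int(c) for c in PROMOTER_CONSENSUS + RBS_MOTIF + "0000" + "000"]
        codons: list[int] = []
        attempts = 0
        while len(codons) < n_codons and attempts < 200 * (n_codons + 1):
            attempts += 1
            order = rng.permutation([2, 3, 4, 5, 6, 7])
            placed = False
            for c in order:
                trip = [(int(c) >> 2) & 1, (int(c) >> 1) & 1, int(c) & 1]
                prefix.extend(trip)
                if any(
                    _tail_makes_motif(prefix, len(prefix) - 3 + j) for j in range(3)
                ):
                    del prefix[-3:]
                else:
                    codons.append(int(c))
                    placed = True
                    break
            if not placed and codons:
                del prefix[-3:]
                codons.pop()
        if len(codons) < n_codons:
            continue
        m, w, h = gray_decode_mwh(codons)
        if w == 0.0 or h == 0.0:
            continue
        gene = PlantedGene(
            codons="".join(format(c, "03b") for c in codons),
            strand=strand,
            mismatches=mismatches,
            mismatch_positions=mismatch_positions,
        )
        if cassette_self_consistent(gene):
            return gene
    raise PlantedSpecError(f"could not grow a clean {n_codons}-codon gene")


def _genome_positions(L: int, strand: int, pos: int, length: int) -> set[int]:
    s = (pos + np.arange(length)) % L
    return set((s if strand == 0 else L - 1 - s).tolist())


def make_planted_genome(
    spec: PlantedGenomeSpec,
    rng: np.random.Generator,
    max_attempts: int = 400,
) -> tuple[Genome, GroundTruth]:
    """Assemble the planted genome and its analytic ground truth.

    Filler blocks are drawn i.i.d. uniform and re-drawn (up to
    ``max_attempts`` targeted resamplings) until the assembled genome carries
    no motif beyond the planted ones; a deterministic all-zero fallback is
    tried last.  Violations inside a cassette itself (e.g. a codon string that
    happens to fold into a terminator) cannot be repaired and raise
    :class:`PlantedSpecError`.
    """
    cassettes = []
    for gene in spec.genes:
        cas = gene.cassette()
        if gene.strand != LEADING:
            cas = "".join("01"[1 - int(c)] for c in reversed(cas))
        cassettes.append(np.frombuffer(cas.encode(), np.uint8) - ord("0"))
    slack = spec.length - sum(c.size for c in cassettes)
    n_fill = len(cassettes) + 1
    sizes = [slack // n_fill + (1 if i < slack % n_fill else 0) for i in range(n_fill)]

    filler = [motif_free_filler(s, rng) for s in sizes]

    def assemble():
        parts = []
        offsets = []
        at = 0
        for i, cas in enumerate(cassettes):
            parts.append(filler[i])
            at += filler[i].size
            offsets.append(at)
            parts.append(cas)
            at += cas.size
        parts.append(filler[-1])
        return np.concatenate(parts).astype(np.uint8), offsets

    bits, offsets = assemble()
    truth = _expected_truth(spec, offsets, spec.length)
    filler_pos = []
    at = 0
    for i in range(n_fill):
        block = set(range(at, at + filler[i].size))
        filler_pos.append(block)
        at += filler[i].size
        if i < len(cassettes):
            at += cassettes[i].size

    for attempt in range(max_attempts):
        bad = _violations(bits, truth)
        relevant = []
        for strand, pos, wlen, hard in bad:
            touched = _genome_positions(spec.length, strand, pos, wlen)
            hit = [i for i in range(n_fill) if touched & filler_pos[i]]
            if not hit:
                if hard:
                    raise PlantedSpecError(
                        "planted cassette itself forms an unplanned motif "
                        f"(strand={strand}, pos={pos}); choose other codons/spacer"
                    )
                continue  # soft motif fully inside cassettes: harmless
            relevant.append(hit)
        if not relevant:
            return Genome(bits=bits), truth
        to_fix = set()
        for hit in relevant:
            to_fix.update(hit)
        for i in to_fix:
            if attempt < max_attempts - 2:
                filler[i] = motif_free_filler(sizes[i], rng)
            else:  # deterministic fallback
                filler[i] = np.zeros(sizes[i], dtype=np.uint8)
        bits, _ = assemble()
    raise PlantedSpecError("could not build motif-free filler; spec too tight")


def cassette_self_consistent(gene: PlantedGene) -> bool:
    """True if the cassette alone (linear scan) introduces no decoding-breaking
    motif: no terminator truncating its own transcript, no second gene start
    inside the transcript, no unplanned promoter window fully inside the
    cassette on either strand.  Junction effects with neighbouring filler are
    handled later by the assembly-level checker."""
    cas = np.frombuffer(gene.cassette().encode(), np.uint8) - ord("0")
    c = cas.size
    tlen = c - PROMOTER_LEN
    # transcript-truncating terminators (reading orientation, linear)
    for i in range(PROMOTER_LEN, c - TERMINATOR_LEN):
        if all(cas[i + j] == 1 - cas[i + 10 - j] for j in range(4)):
            return False
    # extra gene starts inside the transcript
    head = _RBS_BITS + (None,) * RBS_SPACER + (0, 0, 0)
    for i in range(PROMOTER_LEN + 1, c - GENE_HEAD_LEN + 1):
        if all(b is None or cas[i + j] == b for j, b in enumerate(head)):
            return False
    # unplanned promoter windows fully inside the cassette, both orientations
    for seq, skip0 in ((cas, True), ((1 - cas[::-1]).astype(np.uint8), False)):
        for i in range(0, c - PROMOTER_LEN + 1):
            if skip0 and i == 0:
                continue
            d = sum(int(seq[i + j] != _CONSENSUS_BITS[j]) for j in range(PROMOTER_LEN))
            if d <= PROMOTER_MAX_MISMATCH:
                return False
    return True


def make_random_genome(length: int, rng: np.random.Generator) -> Genome:
    """Genome of i.i.d. uniform bits."""
    return Genome.random(length, rng)


def random_planted_spec(
    rng: np.random.Generator,
    length: int = 600,
    n_genes: int | None = None,
    max_tries: int = 200,
) -> PlantedGenomeSpec:
    """Draw a random but realizable planted spec (random strands, promoter
    mismatch counts and codon strings whose cassettes are self-consistent)."""
    if n_genes is None:
        n_genes = int(rng.integers(1, 4))
    for _ in range(max_tries):
        genes = []
        for _ in range(n_genes):
            for _ in range(500):  # redraw codons until the cassette is clean
                n_cod = int(rng.integers(2, 14))
                codons = "".join(
                    format(int(rng.choice([2, 3, 4, 5, 6, 7])), "03b")
                    for _ in range(n_cod)
                )
                d = int(rng.integers(0, PROMOTER_MAX_MISMATCH + 1))
                gene = PlantedGene(
                    codons=codons,
                    strand=int(rng.integers(2)),
                    mismatches=d,
                    mismatch_positions=tuple(
                        int(x) for x in rng.choice(PROMOTER_LEN, size=d, replace=False)
                    ),
                )
                if cassette_self_consistent(gene):
                    break
            else:  # pragma: no cover
                raise PlantedSpecError("could not draw a clean cassette")
            genes.append(gene)
        spec = PlantedGenomeSpec(length=length, genes=tuple(genes))
        # assembly probe: rare cross-gene or junction pathologies reject the spec
        try:
            probe = np.random.default_rng(int(rng.integers(2**31)))
            make_planted_genome(spec, probe, max_attempts=60)
            return spec
        except PlantedSpecError:
            continue
    raise PlantedSpecError("could not draw a realizable planted spec")


# ---------------------------------------------------------------------------
# exhaustive single-event oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX_L = {
    MutationType.SUBSTITUTION: 64,
    MutationType.SMALL_INSERTION: 32,
    MutationType.SMALL_DELETION: 32,
    MutationType.DUPLICATION: 32,
    MutationType.LARGE_DELETION: 32,
    MutationType.TRANSLOCATION: 32,
    MutationType.INVERSION: 32,
}


def _enumerate_events(L: int, mtype: MutationType):
    """Yield (event, probability) over the full single-event space of a type,
    matching the sampling distributions of :func:`bitevol.genome.draw_event`."""
    T = MutationType
    if mtype == T.SUBSTITUTION:
        for p in range(L):
            yield MutationEvent(mtype, p1=p, size=1), 1.0 / L
    elif mtype == T.SMALL_INSERTION:
        for p in range(L):
            for size in range(1, 7):
                for code in range(2**size):
                    payload = np.array(
                        [(code >> (size - 1 - i)) & 1 for i in range(size)],
                        dtype=np.uint8,
                    )
                    yield (
                        MutationEvent(mtype, p1=p, size=size, payload=payload),
                        1.0 / (L * 6 * 2**size),
                    )
    elif mtype == T.SMALL_DELETION:
        for p in range(L):
            for size in range(1, 7):
                yield (
                    MutationEvent(mtype, p1=p, size=size, discarded=size >= L),
                    1.0 / (L * 6),
                )
    elif mtype == T.DUPLICATION:
        for p1 in range(L):
            for p2 in range(L):
                for p3 in range(L):
                    yield (
                        MutationEvent(
                            mtype, p1=p1, p2=p2, p3=p3, size=span_length(L, p1, p2)
                        ),
                        1.0 / L**3,
                    )
    elif mtype == T.LARGE_DELETION:
        for p1 in range(L):
            for p2 in range(L):
                s = span_length(L, p1, p2)
                yield (
                    MutationEvent(mtype, p1=p1, p2=p2, size=s, discarded=s >= L),
                    1.0 / L**2,
                )
    elif mtype == T.TRANSLOCATION:
        for p1 in range(L):
            for p2 in range(L):
                s = span_length(L, p1, p2)
                if s > L - 1:
                    yield (
                        MutationEvent(mtype, p1=p1, p2=p2, size=s, discarded=True),
                        1.0 / L**2,
                    )
                    continue
                n3 = L - s + 1
                for p3 in range(n3):
                    for inv in (False, True):
                        yield (
                            MutationEvent(
                                mtype, p1=p1, p2=p2, p3=p3, size=s, inverted=inv
                            ),
                            1.0 / (L**2 * n3 * 2),
                        )
    elif mtype == T.INVERSION:
        for p1 in range(L):
            for p2 in range(L):
                yield (
                    MutationEvent(mtype, p1=p1, p2=p2, size=span_length(L, p1, p2)),
                    1.0 / L**2,
                )
    else:
        raise ValueError(f"unknown mutation type {mtype}")


def exhaustive_single_event_oracle(
    g: Genome,
    mtype: MutationType,
    target_values: np.ndarray,
    k: float = 1000.0,
) -> tuple[float, int, bool]:
    """Exact neutral fraction among *all* single events of one type.

    Decodes every possible offspring and compares its metabolic error with the
    parent's bit-exactly.  Returns (neutral fraction, number of enumerated
    events, flagged) where ``flagged`` marks a vacuous space (every event
    discarded, fraction trivially 1).
    """
    L = len(g)
    if L > _ORACLE_MAX_L[mtype]:
        raise ValueError(
            f"L={L} exceeds the oracle's search-space guard for {mtype.name}"
        )
    parent_err, _, _ = evaluate_bits(g.bits, target_values, k)
    total_p = 0.0
    neutral_p = 0.0
    n_events = 0
    any_applied = False
    for ev, prob in _enumerate_events(L, mtype):
        n_events += 1
        total_p += prob
        if ev.discarded:
            neutral_p += prob  # no-op offspring is identical to the parent
            continue
        any_applied = True
        child = apply_event(g.bits, ev)
        err, _, _ = evaluate_bits(child, target_values, k)
        if err == parent_err:
            neutral_p += prob
    if not np.isclose(total_p, 1.0, atol=1e-9):  # pragma: no cover - sanity
        warnings.warn(f"oracle probability mass {total_p} != 1")
    return neutral_p / total_p, n_events, not any_applied
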