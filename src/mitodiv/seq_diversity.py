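"""Codon-level nucleotide diversity under the vertebrate mitochondrial code.

Computes synonymous (piS) and nonsynonymous (piN) per-site pairwise
diversity from in-frame codon alignments, using Nei–Gojobori (1986)
equal-weight pathway counting of sites and differences.  The genetic code
is NCBI translation table 2 (vertebrate mitochondrial), in which AGA and
AGG are stop codons and ATA codes for methionine.

The piN/piS ratio is the usual proxy for the efficiency of purifying
selection; it is undefined for species with no synonymous diversity.
"""

from __future__ import annotations

import gzip
import io
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

MITO_VERTEBRATE_TABLE_ID = 2
_CODE = CodonTable.unambiguous_dna_by_id[MITO_VERTEBRATE_TABLE_ID]

_NT = "ACGT"
_PURINES = {"A", "G"}

#: IUPAC nucleotide one-letter codes accepted in input alignments.
IUPAC_NT = set("ACGTURYSWKMBDHVN-.")


def translate(codon: str) -> str | None:
    """Amino acid for ``codon`` under table 2, or ``None`` for a stop."""
    return _CODE.forward_table.get(codon)


def is_stop(codon: str) -> bool:
    return codon in _CODE.stop_codons


def _codon_index(codon: str) -> int:
    return 16 * _NT.index(codon[0]) + 4 * _NT.index(codon[1]) + _NT.index(codon[2])


def _index_codon(idx: int) -> str:
    return _NT[idx // 16] + _NT[(idx // 4) % 4] + _NT[idx % 4]


ALL_CODONS = [_index_codon(i) for i in range(64)]
STOP_CODONS = tuple(_CODE.stop_codons)
CODING_CODONS = [c for c in ALL_CODONS if not is_stop(c)]


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous/nonsynonymous site counts for one codon."""

    syn_sites: float
    nonsyn_sites: float

    def __post_init__(self) -> None:
        if self.syn_sites < 0 or self.nonsyn_sites < 0:
            raise ValueError("site counts must be non-negative")


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent codon alignments."""


@dataclass
class CodonAlignment:
    """An in-frame alignment of coding sequences for one species.

    ``genes`` records provenance as ``(gene_name, (start_codon, end_codon))``
    half-open codon spans into the concatenated alignment.
    """

    species_id: str
    sequences: list[str]
    sequence_ids: list[str]
    genes: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("alignment needs at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise AlignmentError(f"alignment length {length} not divisible by 3")
        if len(self.sequence_ids) != len(self.sequences):
            raise AlignmentError("sequence_ids and sequences differ in length")
        for seq in self.sequences:
            bad = set(seq.upper()) - IUPAC_NT
            if bad:
                raise AlignmentError(f"non-IUPAC symbols in alignment: {sorted(bad)}")
        if not self.genes:
            self.genes = [("gene", (0, self.n_codons))]

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3


@dataclass(frozen=True)
class DiversityEstimate:
    """Per-site pairwise diversity for one species.

    ``ratio`` is ``None`` when the species shows no synonymous diversity,
    in which case it must be excluded from analyses of piN/piS.
    """

    species_id: str
    pi_s: float
    pi_n: float
    ratio: float | None
    n_individuals: int
    n_codons: int

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


# ---------------------------------------------------------------------------
# Nei–Gojobori site and difference counting
# ---------------------------------------------------------------------------

def count_sites(codon: str, *, transversions_only: bool = False) -> SiteCounts:
    """Nei–Gojobori fractional site counts for one codon.

    Each of the nine single-nucleotide neighbours is classified as
    synonymous or not; the synonymous fraction at each position (out of 3
    possible changes) is summed over positions.  Changes to a stop codon
    count as nonsynonymous.  In transversion-only mode only the two
    transversion neighbours per position are considered (fractions out
    of 2), so ``syn_sites + nonsyn_sites`` is 3 in normal mode and 3 in
    tv-mode as well (each position still contributes one site).

    Raises ``ValueError`` for stop codons and codons with non-ACGT symbols.
    """
    codon = codon.upper()
    if any(b not in _NT for b in codon) or len(codon) != 3:
        raise ValueError(f"ambiguous or malformed codon {codon!r}")
    if is_stop(codon):
        raise ValueError(f"stop codon {codon!r} has no site counts")
    aa = translate(codon)
    syn = 0.0
    for pos in range(3):
        changes = [b for b in _NT if b != codon[pos]]
        if transversions_only:
            changes = [b for b in changes if _is_transversion(codon[pos], b)]
        n_syn = 0
        for b in changes:
            alt = codon[:pos] + b + codon[pos + 1 :]
            if not is_stop(alt) and translate(alt) == aa:
                n_syn += 1
        syn += n_syn / len(changes)
    return SiteCounts(syn_sites=syn, nonsyn_sites=3.0 - syn)


def _is_transversion(a: str, b: str) -> bool:
    return (a in _PURINES) != (b in _PURINES)


def _classify_step(c_from: str, c_to: str) -> str:
    """syn/nonsyn for a single-nucleotide step; stops act as a 21st state."""
    aa_from = translate(c_from)
    aa_to = translate(c_to)
    return "syn" if (aa_from is not None and aa_from == aa_to) else "nonsyn"


def _pathway_counts(
    codon_a: str, codon_b: str, *, transversions_only: bool = False
) -> tuple[float, float]:
    """Average (syn_diffs, nonsyn_diffs) between two codons.

    Codons differing at k positions are resolved by averaging the
    synonymous/nonsynonymous assignment of each step over all k! orderings
    of the changes whose intermediate codons avoid stops.  If every
    ordering is blocked by a stop intermediate, all orderings are used
    with steps into or out of a stop counted as nonsynonymous.

    In transversion-only mode, only transversion steps contribute to the
    difference counts (transition steps still occur on the pathway but
    are not counted).
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stop: bool) -> tuple[float, float] | None:
        syn = nonsyn = 0.0
        cur = codon_a
        for step, pos in enumerate(order):
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if is_stop(nxt) and nxt != codon_b and not allow_stop:
                return None
            counted = not transversions_only or _is_transversion(cur[pos], nxt[pos])
            if counted:
                if _classify_step(cur, nxt) == "syn":
                    syn += 1.0
                else:
                    nonsyn += 1.0
            cur = nxt
        return syn, nonsyn

    orders = list(itertools.permutations(diff_pos))
    results = [r for o in orders if (r := walk(o, allow_stop=False)) is not None]
    if not results:
        results = [walk(o, allow_stop=True) for o in orders]
    syn = float(np.mean([r[0] for r in results]))
    nonsyn = float(np.mean([r[1] for r in results]))
    return syn, nonsyn


def pairwise_counts(
    seq_a: str, seq_b: str, *, transversions_only: bool = False
) -> tuple[float, float, float, float]:
    """Nei–Gojobori counts between two equal-length in-frame sequences.

    Returns ``(syn_diffs, nonsyn_diffs, syn_sites, nonsyn_sites)``.  Site
    counts are averaged over the two sequences.  Codons containing gaps,
    ambiguity codes or stop codons in either sequence are excluded
    pairwise (from both the difference and the site totals).
    """
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences differ in length")
    if len(seq_a) % 3 != 0:
        raise AlignmentError("sequence length not divisible by 3")
    a = encode_codons(seq_a)
    b = encode_codons(seq_b)
    return _pairwise_counts_encoded(a, b, _tables(transversions_only))


# Lookup tables over codon-index pairs; built once per mode.
class _NGTables:
    def __init__(self, transversions_only: bool):
        syn_sites = np.full(64, np.nan)
        nonsyn_sites = np.full(64, np.nan)
        for c in CODING_CODONS:
            sc = count_sites(c, transversions_only=transversions_only)
            idx = _codon_index(c)
            syn_sites[idx] = sc.syn_sites
            nonsyn_sites[idx] = sc.nonsyn_sites
        syn_d = np.zeros(64 * 64)
        nonsyn_d = np.zeros(64 * 64)
        for ca in CODING_CODONS:
            for cb in CODING_CODONS:
                s, n = _pathway_counts(ca, cb, transversions_only=transversions_only)
                syn_d[_codon_index(ca) * 64 + _codon_index(cb)] = s
                nonsyn_d[_codon_index(ca) * 64 + _codon_index(cb)] = n
        self.syn_sites = syn_sites
        self.nonsyn_sites = nonsyn_sites
        self.syn_diffs = syn_d
        self.nonsyn_diffs = nonsyn_d
        # codons usable in pairwise comparisons (coding only)
        self.valid = ~np.isnan(syn_sites)


_TABLE_CACHE: dict[bool, _NGTables] = {}


def _tables(transversions_only: bool = False) -> _NGTables:
    if transversions_only not in _TABLE_CACHE:
        _TABLE_CACHE[transversions_only] = _NGTables(transversions_only)
    return _TABLE_CACHE[transversions_only]


_BYTE_TO_NT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_NT):
    _BYTE_TO_NT[ord(_b)] = _i
    _BYTE_TO_NT[ord(_b.lower())] = _i


def encode_codons(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int codon indices (0–63; -1 invalid).

    Codons containing any non-ACGT symbol (gap, ambiguity) are -1.
    Stop codons keep their index here; they are masked during pairwise
    comparison.
    """
    raw = _BYTE_TO_NT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    trip = raw.reshape(-1, 3).astype(np.int32)
    idx = 16 * trip[:, 0] + 4 * trip[:, 1] + trip[:, 2]
    idx[(trip >= 4).any(axis=1)] = -1
    return idx


def _pairwise_counts_encoded(
    a: np.ndarray, b: np.ndarray, tab: _NGTables
) -> tuple[float, float, float, float]:
    mask = (a >= 0) & (b >= 0)
    if mask.any():
        mask &= tab.valid[np.where(mask, a, 0)] & tab.valid[np.where(mask, b, 0)]
    aa = a[mask]
    bb = b[mask]
    pair_idx = aa * 64 + bb
    syn_d = float(tab.syn_diffs[pair_idx].sum())
    nonsyn_d = float(tab.nonsyn_diffs[pair_idx].sum())
    syn_s = float((tab.syn_sites[aa] + tab.syn_sites[bb]).sum() / 2.0)
    nonsyn_s = float((tab.nonsyn_sites[aa] + tab.nonsyn_sites[bb]).sum() / 2.0)
    return syn_d, nonsyn_d, syn_s, nonsyn_s


# ---------------------------------------------------------------------------
# Alignment I/O
# ---------------------------------------------------------------------------

def read_alignment(
    fasta_text: str,
    frame_offset: int = 0,
    *,
    species_id: str = "unknown",
    gene: str = "gene",
) -> CodonAlignment:
    """Parse a pre-aligned FASTA into a codon alignment.

    ``frame_offset`` (0–2) drops leading bases to restore the reading
    frame; trailing bases beyond the last whole codon are trimmed.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    records = list(SeqIO.parse(io.StringIO(fasta_text), "fasta"))
    if not records:
        raise AlignmentError("no FASTA records found")
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal record lengths: {sorted(lengths)}")
    trimmed = []
    for s in seqs:
        s = s[frame_offset:]
        s = s[: len(s) - len(s) % 3]
        trimmed.append(s)
    return CodonAlignment(
        species_id=species_id,
        sequences=trimmed,
        sequence_ids=[r.id for r in records],
        genes=[(gene, (0, len(trimmed[0]) // 3))],
    )


def read_alignment_file(
    path: str | Path, frame_offset: int = 0, *, species_id: str = "unknown",
    gene: str = "gene",
) -> CodonAlignment:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            text = fh.read()
    else:
        text = path.read_text()
    return read_alignment(text, frame_offset, species_id=species_id, gene=gene)


def concatenate_genes(alignments: Sequence[CodonAlignment]) -> CodonAlignment:
    """Concatenate per-gene alignments of the same individuals.

    All alignments must cover the same set of sequence ids; sequences are
    matched by id, and per-gene codon spans are recorded.
    """
    if not alignments:
        raise AlignmentError("nothing to concatenate")
    if len(alignments) == 1:
        return alignments[0]
    first = alignments[0]
    id_set = set(first.sequence_ids)
    for aln in alignments[1:]:
        if set(aln.sequence_ids) != id_set:
            raise AlignmentError(
                f"individual sets differ between genes for {first.species_id}: "
                f"{sorted(id_set ^ set(aln.sequence_ids))}"
            )
    order = first.sequence_ids
    parts: dict[str, list[str]] = {sid: [] for sid in order}
    genes: list[tuple[str, tuple[int, int]]] = []
    offset = 0
    for aln in alignments:
        by_id = dict(zip(aln.sequence_ids, aln.sequences))
        for sid in order:
            parts[sid].append(by_id[sid])
        for name, (lo, hi) in aln.genes:
            genes.append((name, (offset + lo, offset + hi)))
        offset += aln.n_codons
    return CodonAlignment(
        species_id=first.species_id,
        sequences=["".join(parts[sid]) for sid in order],
        sequence_ids=list(order),
        genes=genes,
    )


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def diversity(alignment: CodonAlignment) -> DiversityEstimate:
    """Average pairwise piS and piN over all sequence pairs.

    piS is the mean over the n(n-1)/2 pairs of synonymous differences per
    synonymous site (Nei–Gojobori counts); piN analogously.  No
    multiple-hit correction is applied: within-species diversities are
    far below saturation.  The piN/piS ratio is undefined when piS = 0.
    """
    n = alignment.n_sequences
    if n < 2:
        raise AlignmentError("diversity needs at least 2 sequences")
    tab = _tables(False)
    enc = np.stack([encode_codons(s) for s in alignment.sequences])
    ii, jj = np.triu_indices(n, k=1)
    A = enc[ii]  # (n_pairs, L)
    B = enc[jj]
    mask = (A >= 0) & (B >= 0)
    A0 = np.where(mask, A, 0)
    B0 = np.where(mask, B, 0)
    mask &= tab.valid[A0] & tab.valid[B0]
    pair_idx = np.where(mask, A0 * 64 + B0, 0)
    sd = np.where(mask, tab.syn_diffs[pair_idx], 0.0).sum(axis=1)
    nd = np.where(mask, tab.nonsyn_diffs[pair_idx], 0.0).sum(axis=1)
    ss = np.where(mask, (tab.syn_sites[A0] + tab.syn_sites[B0]) / 2.0, 0.0).sum(axis=1)
    ns = np.where(mask, (tab.nonsyn_sites[A0] + tab.nonsyn_sites[B0]) / 2.0,
                  0.0).sum(axis=1)
    ok = (ss > 0) & (ns > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning(
            "species %s: %d pairs with no comparable codons skipped",
            alignment.species_id, n_bad,
        )
    ps_vals = (sd[ok] / ss[ok]).tolist()
    pn_vals = (nd[ok] / ns[ok]).tolist()
    if not ps_vals:
        raise AlignmentError(
            f"species {alignment.species_id}: no comparable sequence pairs"
        )
    pi_s = float(np.mean(ps_vals))
    pi_n = float(np.mean(pn_vals))
    ratio = pi_n / pi_s if pi_s > 0 else None
    return DiversityEstimate(
        species_id=alignment.species_id,
        pi_s=pi_s,
        pi_n=pi_n,
        ratio=ratio,
        n_individuals=n,
        n_codons=alignment.n_codons,
    )


MIN_INDIVIDUALS = 4


def diversity_table(
    alignments: Iterable[CodonAlignment],
    *,
    min_individuals: int = MIN_INDIVIDUALS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species diversity table with the minimum-sample-size filter.

    Species with fewer than ``min_individuals`` sequenced individuals are
    excluded (the inclusion rule of the underlying study design).  Returns
    ``(table, exclusions)``; the exclusion frame has columns
    ``species, reason``.
    """
    rows = []
    excluded = []
    for aln in alignments:
        if aln.n_sequences < min_individuals:
            excluded.append(
                {"species": aln.species_id, "reason": "min-individuals"}
            )
            continue
        est = diversity(aln)
        rows.append(
            {
                "species": est.species_id,
                "n_individuals": est.n_individuals,
                "n_codons": est.n_codons,
                "pi_s": est.pi_s,
                "pi_n": est.pi_n,
                "pi_n_over_pi_s": est.ratio if est.ratio is not None else np.nan,
            }
        )
    if excluded:
        logger.info("excluded %d species below %d individuals", len(excluded),
                    min_individuals)
    table = pd.DataFrame(
        rows,
        columns=["species", "n_individuals", "n_codons", "pi_s", "pi_n",
                 "pi_n_over_pi_s"],
    )
    exclusions = pd.DataFrame(excluded, columns=["species", "reason"])
    return table, exclusions
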