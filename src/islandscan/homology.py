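"""Protein homology detection.

A self-contained local-alignment search (affine gaps, BLOSUM62, Karlin-
Altschul E-values) for desk-scale runs, plus an ingester for the 12-column
tabular homology dialect produced by external search tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .genome import Genome

# Published Karlin-Altschul parameters for gapped BLOSUM62, open 11 / extend 1.
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_KAPPA = 0.041
BLOSUM62_GAPPED_H = 0.14


class TabularParseError(ValueError):
    """Raised on a malformed 12-column tabular homology file."""


@dataclass
class ScoringScheme:
    """Substitution matrix with affine gap penalties and E-value constants.

    Gap convention matches BLAST: a gap of length k costs
    ``gap_open + k * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = BLOSUM62_GAPPED_LAMBDA
    kappa: float = BLOSUM62_GAPPED_KAPPA
    entropy: float = BLOSUM62_GAPPED_H

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be > 0")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("lambda and kappa must be > 0")
        self._matrix = substitution_matrices.load(self.matrix_name)

    @property
    def matrix(self):
        return self._matrix

    def substitution(self, a: str, b: str) -> float:
        return float(self._matrix[a, b])


@dataclass
class SearchThresholds:
    evalue_max: float = 1e-5
    min_aln_len: int = 0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")


@dataclass
class HomologyHit:
    query_id: str
    subject_feature_id: str
    genome_id: str
    score: float
    bitscore: float
    evalue: float
    identity_frac: float
    query_span: tuple[int, int] = (0, 0)
    subject_span: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not 0.0 <= self.identity_frac <= 1.0:
            raise ValueError("identity_frac must lie in [0, 1]")


@dataclass
class AlignmentResult:
    score: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    identity_frac: float
    aln_len: int


def _make_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = scheme.matrix
    # PairwiseAligner charges open_gap_score for the first gapped position:
    # length-k gap cost = open + k*extend requires open_score = -(open+extend).
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


_MATRIX_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _sanitize(seq: str) -> str:
    s = seq.upper()
    return "".join(c if c in _MATRIX_ALPHABET else "X" for c in s)


def local_align(query_seq: str, subject_seq: str,
                scheme: Optional[ScoringScheme] = None) -> AlignmentResult:
    """Optimal local alignment under affine gaps (Gotoh) with traceback.

    Returns the raw score, aligned spans (0-based half-open) and the
    identity fraction (identical columns / alignment columns).
    """
    scheme = scheme or ScoringScheme()
    q, s = _sanitize(query_seq), _sanitize(subject_seq)
    if not q or not s:
        return AlignmentResult(0.0, (0, 0), (0, 0), 0.0, 0)
    aligner = _make_aligner(scheme)
    score = float(aligner.score(q, s))
    if score <= 0:
        return AlignmentResult(max(score, 0.0), (0, 0), (0, 0), 0.0, 0)
    aln = aligner.align(q, s)[0]
    qa, sa = aln.aligned
    matches = 0
    for (qs, qe), (ss, se) in zip(qa, sa):
        matches += sum(1 for a, b in zip(q[qs:qe], s[ss:se]) if a == b)
    aln_len = aln.length
    q_span = (int(qa[0][0]), int(qa[-1][1]))
    s_span = (int(sa[0][0]), int(sa[-1][1]))
    identity = matches / aln_len if aln_len else 0.0
    return AlignmentResult(score, q_span, s_span, identity, aln_len)


def length_adjustment(m: int, n: int, scheme: ScoringScheme,
                      n_seqs: int = 1, iterations: int = 20) -> int:
    """Edge-effect length correction l solving l = ln(K m' n')/H iteratively."""
    ell = 0.0
    for _ in range(iterations):
        m_eff = max(1.0, m - ell)
        n_eff = max(1.0, n - n_seqs * ell)
        val = math.log(scheme.kappa * m_eff * n_eff) / scheme.entropy
        ell = max(0.0, val)
    return int(ell)


def evalue(score: float, query_len: int, db_len: int,
           scheme: Optional[ScoringScheme] = None,
           n_seqs: int = 1, mode: str = "simple") -> float:
    """Karlin-Altschul expectation E = K * m' * n' * exp(-lambda * S)."""
    scheme = scheme or ScoringScheme()
    if query_len <= 0 or db_len <= 0:
        raise ValueError("query_len and db_len must be > 0")
    if mode == "simple":
        ell = 0
    elif mode == "corrected":
        ell = length_adjustment(query_len, db_len, scheme, n_seqs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    m_eff = max(1, query_len - ell)
    n_eff = max(1, db_len - n_seqs * ell)
    return scheme.kappa * m_eff * n_eff * math.exp(-scheme.lam * score)


def bitscore(score: float, scheme: Optional[ScoringScheme] = None) -> float:
    scheme = scheme or ScoringScheme()
    return (scheme.lam * score - math.log(scheme.kappa)) / math.log(2)


def _load_queries(queries) -> dict[str, str]:
    if isinstance(queries, dict):
        return dict(queries)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(queries), "fasta")}


def search(queries, genomes: Iterable[Genome],
           scheme: Optional[ScoringScheme] = None,
           thresholds: Optional[SearchThresholds] = None,
           evalue_mode: str = "simple") -> list[HomologyHit]:
    """Search query proteins against all CDS proteins of the given genomes.

    One best hit per (query, CDS); hits with E < ``evalue_max`` are returned
    in deterministic (genome_id, replicon_id, start) order.

    ``queries`` is a protein FASTA path or a {query_id: sequence} mapping.
    """
    scheme = scheme or ScoringScheme()
    thresholds = thresholds or SearchThresholds()
    qmap = _load_queries(queries)
    genomes = list(genomes)

    subjects = []  # (genome_id, replicon_id, start, feature)
    for g in genomes:
        for feat in g.features_sorted():
            if feat.protein_seq:
                subjects.append((g.assembly_id, feat.replicon_id, feat.start, feat))
    if not subjects:
        raise ValueError(
            "no protein sequences available in the genome collection; "
            "supply a protein FASTA or enable CDS translation in read_genome"
        )
    db_len = sum(len(feat.protein_seq) for _, _, _, feat in subjects)
    n_seqs = len(subjects)

    hits: list[HomologyHit] = []
    for query_id, qseq in qmap.items():
        for genome_id, rep_id, start, feat in subjects:
            res = local_align(qseq, feat.protein_seq, scheme)
            if res.aln_len < thresholds.min_aln_len or res.score <= 0:
                continue
            e = evalue(res.score, len(qseq), db_len, scheme,
                       n_seqs=n_seqs, mode=evalue_mode)
            if e < thresholds.evalue_max:
                hits.append(HomologyHit(
                    query_id=query_id,
                    subject_feature_id=feat.feature_id,
                    genome_id=genome_id,
                    score=res.score,
                    bitscore=bitscore(res.score, scheme),
                    evalue=e,
                    identity_frac=res.identity_frac,
                    query_span=res.query_span,
                    subject_span=res.subject_span,
                ))
    order = {
        (gid, feat.feature_id): (gid, rid, start)
        for gid, rid, start, feat in subjects
    }
    hits.sort(key=lambda h: order[(h.genome_id, h.subject_feature_id)] + (h.query_id,))
    return hits


def ingest_tabular(path: str | Path,
                   thresholds: Optional[SearchThresholds] = None) -> list[HomologyHit]:
    """Read 12-column tabular homology results (query, subject, %identity,
    aln length, mismatches, gap opens, qstart, qend, sstart, send, evalue,
    bitscore; 1-based inclusive coordinates) and filter by thresholds.

    Subject ids of the form ``assembly|feature_id`` populate genome_id.
    """
    thresholds = thresholds or SearchThresholds()
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise TabularParseError(
                    f"{path}:{lineno}: expected 12 columns, found {len(cols)}"
                )
            try:
                (query, subject, pident, aln_len, _mm, _go,
                 qs, qe, ss, se, ev, bits) = cols
                pident_f = float(pident)
                aln_len_i = int(aln_len)
                qs_i, qe_i, ss_i, se_i = int(qs), int(qe), int(ss), int(se)
                ev_f, bits_f = float(ev), float(bits)
            except ValueError as exc:
                raise TabularParseError(f"{path}:{lineno}: {exc}") from exc
            if ev_f >= thresholds.evalue_max or aln_len_i < thresholds.min_aln_len:
                continue
            genome_id, feature_id = "", subject
            if "|" in subject:
                genome_id, feature_id = subject.split("|", 1)
            hits.append(HomologyHit(
                query_id=query,
                subject_feature_id=feature_id,
                genome_id=genome_id,
                score=0.0,
                bitscore=bits_f,
                evalue=ev_f,
                identity_frac=pident_f / 100.0,
                query_span=(qs_i - 1, qe_i),
                subject_span=(min(ss_i, se_i) - 1, max(ss_i, se_i)),
            ))
    return hits


HITS_TSV_COLUMNS = [
    "query_id", "subject_feature_id", "genome_id", "score", "bitscore",
    "evalue", "identity_frac", "qstart", "qend", "sstart", "send",
]


def write_hits_tsv(hits: Iterable[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HITS_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_feature_id, h.genome_id,
                f"{h.score:g}", f"{h.bitscore:.4g}", f"{h.evalue:.6g}",
                f"{h.identity_frac:.6g}",
                h.query_span[0] + 1, h.query_span[1],
                h.subject_span[0] + 1, h.subject_span[1],
            ])) + "\n")
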