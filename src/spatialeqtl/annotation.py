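"""Regulatory annotation: histone-mark overlap, PWM allele scoring, LD stats."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragments import Variant

log = logging.getLogger(__name__)

__all__ = [
    "HistoneMarkRecord",
    "PWM",
    "MotifHit",
    "LDStats",
    "DEFAULT_MARK_CLASSES",
    "histone_overlap",
    "score_allele_against_pwm",
    "motif_delta",
    "ld_matrix",
    "read_marks_tsv",
    "write_marks_tsv",
    "read_pwms",
    "write_pwms",
    "read_haplotypes_tsv",
    "reverse_complement",
]

#: Mark -> assay class grouping used for enhancer/promoter calls.
DEFAULT_MARK_CLASSES: dict[str, str] = {
    "H3K4ac": "enhancer",
    "H3K4me1": "enhancer",
    "H3K27ac": "enhancer",
    "H3K4me3": "promoter",
    "H3K9ac": "promoter",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HistoneMarkRecord:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    tissue: str
    mark: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty mark interval")


@dataclass
class PWM:
    """Position probability matrix, rows = positions, columns = A,C,G,T."""

    motif_name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError("PWM must be an Lx4 matrix with L >= 1")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.motif_name}: rows must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_name, self.probs[::-1, ::-1], self.background[::-1])


@dataclass
class MotifHit:
    motif_name: str
    ref_score: float
    alt_score: float
    delta: float
    best_offset: int
    best_strand: str


@dataclass(frozen=True)
class LDStats:
    rsid_a: str
    rsid_b: str
    r2: float
    d_prime: float


# ---------------------------------------------------------------------------
# histone marks


def histone_overlap(
    variant: Variant,
    marks: list[HistoneMarkRecord],
    tissues: set[str] | None = None,
    mark_classes: dict[str, str] | None = None,
) -> dict[str, dict]:
    """Marks covering the variant per tissue, plus enhancer/promoter calls.

    A mark covers the variant iff its half-open interval contains the 0-based
    position. Marks not present in the grouping are classed "other" and
    logged. Returns {tissue: {"marks": set, "enhancer": bool, "promoter": bool}}.
    """
    classes = DEFAULT_MARK_CLASSES if mark_classes is None else mark_classes
    out: dict[str, dict] = {}
    for m in marks:
        if m.chrom != variant.chrom or not (m.start <= variant.pos0 < m.end):
            continue
        if tissues is not None and m.tissue not in tissues:
            continue
        cls = classes.get(m.mark)
        if cls is None:
            log.warning("mark %s not in grouping; classed 'other'", m.mark)
            cls = "other"
        entry = out.setdefault(
            m.tissue, {"marks": set(), "enhancer": False, "promoter": False}
        )
        entry["marks"].add(m.mark)
        if cls == "enhancer":
            entry["enhancer"] = True
        elif cls == "promoter":
            entry["promoter"] = True
    return out


# ---------------------------------------------------------------------------
# PWM scoring


def _score_window(window: str, pwm: PWM, pseudocount: float) -> float:
    probs = pwm.probs + pseudocount
    if pseudocount:
        probs = probs / probs.sum(axis=1, keepdims=True)
    total = 0.0
    for i, base in enumerate(window):
        j = _BASE_INDEX[base]
        total += np.log2(probs[i, j] / pwm.background[j])
    return total


def score_allele_against_pwm(
    context: str,
    offset: int,
    allele: str,
    pwm: PWM,
    pseudocount: float = 0.0,
    with_position: bool = False,
):
    """Best log2-odds score of the allele-substituted context against a PWM.

    Maximised over every placement whose window covers the variant offset and
    over both strands (the minus strand scores the reverse complement of the
    window). Scores are sum_i log2(probs[i, base_i] / background[base_i]).
    """
    seq = context.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("context must contain only A/C/G/T")
    if not 0 <= offset < len(seq):
        raise ValueError("variant offset outside context")
    allele = allele.upper()
    if allele not in _BASE_INDEX:
        raise ValueError(f"bad allele {allele!r}")
    seq = seq[:offset] + allele + seq[offset + 1 :]

    L = len(pwm)
    lo = max(0, offset - L + 1)
    hi = min(offset, len(seq) - L)
    if hi < lo:
        raise ValueError("context too short for every motif placement covering the variant")
    best = -np.inf
    best_pos, best_strand = lo, "+"
    for p in range(lo, hi + 1):
        window = seq[p : p + L]
        for strand, w in (("+", window), ("-", reverse_complement(window))):
            s = _score_window(w, pwm, pseudocount)
            if s > best:
                best, best_pos, best_strand = s, p, strand
    if with_position:
        return best, best_pos, best_strand
    return best


def motif_delta(
    context: str,
    offset: int,
    ref: str,
    alt: str,
    pwms: list[PWM],
    pseudocount: float = 0.0,
) -> list[MotifHit]:
    """Reference vs alternative allele score for each PWM.

    delta = alt_score - ref_score; the per-allele maxima may occur at
    different offsets/strands. delta < 0 predicts decreased binding affinity
    for the alternate allele.
    """
    hits: list[MotifHit] = []
    for pwm in pwms:
        ref_score = score_allele_against_pwm(context, offset, ref, pwm, pseudocount)
        alt_score, pos, strand = score_allele_against_pwm(
            context, offset, alt, pwm, pseudocount, with_position=True
        )
        hits.append(
            MotifHit(
                motif_name=pwm.motif_name,
                ref_score=float(ref_score),
                alt_score=float(alt_score),
                delta=float(alt_score - ref_score),
                best_offset=pos,
                best_strand=strand,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _ld_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pa = a.mean()
    pb = b.mean()
    pab = np.mean(a * b)
    d = pab - pa * pb
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return float(r2), 0.0
    return float(r2), float(abs(d) / dmax)


def ld_matrix(haplotypes: pd.DataFrame, rsids: list[str] | None = None) -> list[LDStats]:
    """Pairwise r^2 and D' from a phased binary haplotype panel.

    ``haplotypes``: rows = haplotypes, columns = variant rsIDs, values 0/1.
    Monomorphic variants are rejected by name. Includes the diagonal
    (r2 = D' = 1 for polymorphic variants).
    """
    if rsids is None:
        rsids = list(haplotypes.columns)
    cols = {}
    for rsid in rsids:
        if rsid not in haplotypes.columns:
            raise KeyError(f"variant {rsid} absent from haplotype panel")
        col = haplotypes[rsid].to_numpy(dtype=float)
        if np.any((col != 0) & (col != 1)) or np.any(~np.isfinite(col)):
            raise ValueError(f"variant {rsid}: haplotype values must be 0/1")
        if col.min() == col.max():
            raise ValueError(f"variant {rsid} is monomorphic in the panel")
        cols[rsid] = col
    out: list[LDStats] = []
    for i, a in enumerate(rsids):
        for b in rsids[i:]:
            if a == b:
                out.append(LDStats(a, b, 1.0, 1.0))
            else:
                r2, dp = _ld_pair(cols[a], cols[b])
                out.append(LDStats(a, b, r2, dp))
    return out


# ---------------------------------------------------------------------------
# I/O


def read_marks_tsv(path) -> list[HistoneMarkRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tissue": str, "mark": str})
    return [
        HistoneMarkRecord(r.chrom, int(r.start), int(r.end), r.tissue, r.mark)
        for r in df.itertuples()
    ]


def write_marks_tsv(marks: list[HistoneMarkRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\ttissue\tmark\n")
        for m in marks:
            fh.write(f"{m.chrom}\t{m.start}\t{m.end}\t{m.tissue}\t{m.mark}\n")


def read_pwms(path) -> list[PWM]:
    """Parse the PWM text format: '>NAME' header followed by L lines of four
    probabilities in column order A C G T."""
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []

    def flush():
        if name is not None:
            if not rows:
                raise ValueError(f"PWM {name} has no rows")
            pwms.append(PWM(name, np.array(rows)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                rows = []
            else:
                if name is None:
                    raise ValueError("PWM rows before any '>' header")
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(f"PWM {name}: expected 4 probabilities per row")
                rows.append(vals)
    flush()
    return pwms


def write_pwms(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_name}\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def read_haplotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
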