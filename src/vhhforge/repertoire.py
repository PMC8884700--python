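"""VHH library characterisation.

Full-length filtering, cardinality (counts-of-counts) spectrum,
zero-truncated negative-binomial diversity estimation and the Gaussian fit
of translated lengths.
"""

from __future__ import annotations

import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio import SeqIO
from scipy.optimize import minimize
from scipy.special import expit, gammaln

__all__ = [
    "RepertoireRecord",
    "CardinalitySpectrum",
    "DiversityEstimate",
    "LengthFit",
    "read_sequences",
    "filter_full_length",
    "cardinality_spectrum",
    "fit_truncated_nb",
    "ztnb_logpmf",
    "fit_length_gaussian",
]


@dataclass
class RepertoireRecord:
    """One distinct sequence with its accumulated read count."""

    id: str
    nt_seq: str | None = None
    aa_seq: str | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if self.nt_seq is None and self.aa_seq is None:
            raise ValueError("at least one of nt_seq/aa_seq must be present")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class CardinalitySpectrum:
    """Counts-of-counts: f[k] = number of distinct sequences seen k times."""

    f: dict

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.f):
            raise ValueError("cardinalities must be >= 1")

    @property
    def n_unique(self) -> int:
        return int(sum(self.f.values()))

    @property
    def total_reads(self) -> int:
        return int(sum(k * v for k, v in self.f.items()))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        ks = np.array(sorted(self.f), dtype=float)
        fs = np.array([self.f[int(k)] for k in ks], dtype=float)
        return ks, fs


@dataclass
class DiversityEstimate:
    """Zero-truncated NB fit of the cardinality spectrum and the implied
    unseen-species extrapolation U / (1 - p0)."""

    observed_unique: int
    nb_r: float
    nb_p: float
    p0: float
    estimated_total: float
    loglik: float
    converged: bool
    message: str = ""

    def to_json(self) -> dict:
        return {
            "observed_unique": self.observed_unique,
            "nb_r": self.nb_r,
            "nb_p": self.nb_p,
            "p0": self.p0,
            "estimated_total": self.estimated_total,
            "loglik": self.loglik,
            "converged": self.converged,
            "message": self.message,
        }


@dataclass
class LengthFit:
    mean: float
    sd: float
    n: int


# ---------------------------------------------------------------------------
# I/O


def read_sequences(path: str, fmt: str | None = None) -> list[RepertoireRecord]:
    """Read FASTA/FASTQ reads; identical sequences collapse with counts
    accumulated and the id of the first occurrence kept."""
    if fmt is None:
        low = str(path).lower()
        fmt = "fastq" if low.endswith((".fastq", ".fq")) else "fasta"
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    counts: Counter = Counter()
    first_id: dict[str, str] = {}
    order: list[str] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seq = str(rec.seq).upper()
            if seq not in counts:
                first_id[seq] = rec.id
                order.append(seq)
            counts[seq] += 1
    except ValueError as exc:
        raise ValueError(f"{path}: malformed {fmt} record: {exc}") from exc
    if not counts:
        warnings.warn(f"{path}: no sequences found", stacklevel=2)
        return []
    return [RepertoireRecord(id=first_id[s], nt_seq=s, count=counts[s]) for s in order]


# ---------------------------------------------------------------------------
# Full-length filter


def filter_full_length(
    records,
    frame_offset: int = 0,
    min_aa: int = 90,
    max_aa: int = 150,
) -> tuple[list[RepertoireRecord], dict]:
    """Keep records that are in frame, free of internal stops and of
    plausible translated length; report counts per rejection reason.

    A single trailing stop codon is tolerated (ordinary CDS ending).
    """
    kept: list[RepertoireRecord] = []
    report = {"input": 0, "kept": 0, "frameshift": 0, "premature_stop": 0,
              "length": 0, "ambiguous": 0}
    for rec in records:
        if rec.nt_seq is None:
            raise ValueError(f"record {rec.id} has no nucleotide sequence")
        report["input"] += 1
        nt = rec.nt_seq.upper()
        if set(nt) - set("ACGT"):
            report["ambiguous"] += 1
            continue
        if (len(nt) - frame_offset) % 3 != 0:
            report["frameshift"] += 1
            continue
        aa = str(Seq(nt[frame_offset:]).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            report["premature_stop"] += 1
            continue
        if not (min_aa <= len(aa) <= max_aa):
            report["length"] += 1
            continue
        kept.append(RepertoireRecord(id=rec.id, nt_seq=rec.nt_seq,
                                     aa_seq=aa, count=rec.count))
        report["kept"] += 1
    return kept, report


# ---------------------------------------------------------------------------
# Cardinality spectrum and diversity fit


def cardinality_spectrum(records) -> CardinalitySpectrum:
    f: Counter = Counter()
    for rec in records:
        f[int(rec.count)] += 1
    return CardinalitySpectrum(dict(f))


def _nb_logpmf(k: np.ndarray, r: float, logp: float, log1mp: float) -> np.ndarray:
    # NB(k; r, p) = C(k+r-1, k) p^r (1-p)^k with continuous r
    return (gammaln(k + r) - gammaln(r) - gammaln(k + 1.0)
            + r * logp + k * log1mp)


def ztnb_logpmf(k, r: float, p: float):
    """log pmf of the zero-truncated NB: NB(k; r, p) / (1 - p^r), k >= 1."""
    k = np.asarray(k, dtype=float)
    logp, log1mp = math.log(p), math.log1p(-p)
    log_trunc = math.log1p(-math.exp(r * logp)) if r * logp < -1e-12 else -np.inf
    return _nb_logpmf(k, r, logp, log1mp) - log_trunc


def ztnb_loglik(spectrum: CardinalitySpectrum, r: float, p: float) -> float:
    ks, fs = spectrum.arrays()
    return float((fs * ztnb_logpmf(ks, r, p)).sum())


def fit_truncated_nb(spectrum: CardinalitySpectrum) -> DiversityEstimate:
    """Maximum-likelihood zero-truncated NB fit of a cardinality spectrum.

    Optimises (log r, logit p) with bounded quasi-Newton from five
    deterministic starts; the best likelihood wins (ties to smallest r).
    estimated_total = U / (1 - p0) with p0 = p_hat ** r_hat.
    """
    if not spectrum.f:
        raise ValueError("empty spectrum")
    if len(spectrum.f) < 2:
        raise ValueError(
            "unidentifiable spectrum: need at least two distinct cardinalities")
    ks, fs = spectrum.arrays()
    u = spectrum.n_unique

    def nll(theta: np.ndarray) -> float:
        r = math.exp(theta[0])
        p = expit(theta[1])
        logp, log1mp = math.log(p), math.log1p(-p)
        rlogp = r * logp
        if rlogp > -1e-300:
            return 1e300
        log_trunc = math.log1p(-math.exp(rlogp)) if rlogp > -700 else 0.0
        ll = (fs * (_nb_logpmf(ks, r, logp, log1mp) - log_trunc)).sum()
        return -ll if np.isfinite(ll) else 1e300

    # moment-flavoured start plus a fixed grid
    mean = spectrum.total_reads / u
    var = float((fs * (ks - mean) ** 2).sum() / max(u - 1, 1))
    if var > mean:
        p_mom = min(max(mean / var, 1e-3), 1 - 1e-3)
        r_mom = max(mean * p_mom / (1.0 - p_mom), 1e-3)
    else:
        p_mom, r_mom = 0.5, 1.0
    starts = [
        (math.log(r_mom), math.log(p_mom / (1 - p_mom))),
        (math.log(0.5), 0.0),
        (math.log(1.0), math.log(0.6 / 0.4)),
        (math.log(3.0), math.log(0.3 / 0.7)),
        (math.log(0.2), math.log(0.8 / 0.2)),
    ]
    bounds = [(-12.0, 12.0), (-12.0, 12.0)]
    best = None
    any_converged = False
    message = ""
    for x0 in starts:
        res = minimize(nll, np.array(x0), method="L-BFGS-B", bounds=bounds)
        r_hat = math.exp(res.x[0])
        cand = (res.fun, r_hat, expit(res.x[1]), res.success, str(res.message))
        if best is None or cand[0] < best[0] - 1e-9 or (
                abs(cand[0] - best[0]) <= 1e-9 and cand[1] < best[1]):
            best = cand
        any_converged = any_converged or res.success
    fun, r_hat, p_hat, success, message = best
    loglik = -float(fun)
    p0 = p_hat ** r_hat
    converged = bool(any_converged and np.isfinite(loglik))
    return DiversityEstimate(
        observed_unique=u,
        nb_r=float(r_hat),
        nb_p=float(p_hat),
        p0=float(p0),
        estimated_total=float(u / (1.0 - p0)),
        loglik=loglik,
        converged=converged,
        message="" if converged else message,
    )


# ---------------------------------------------------------------------------
# Length fit


def fit_length_gaussian(records, weighting: str = "unique") -> LengthFit:
    """Maximum-likelihood Gaussian over amino-acid lengths.

    ``unique`` weights every distinct sequence once (per-protein framing);
    ``read-weighted`` weights by read count.  Population (ML) standard
    deviation.
    """
    if weighting not in ("unique", "read-weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    lengths, weights = [], []
    for rec in records:
        aa = rec.aa_seq
        if aa is None:
            if rec.nt_seq is None:
                continue
            aa = str(Seq(rec.nt_seq).translate())
            if aa.endswith("*"):
                aa = aa[:-1]
        lengths.append(len(aa))
        weights.append(1.0 if weighting == "unique" else float(rec.count))
    if len(lengths) < 2:
        raise ValueError("need at least 2 sequences with amino-acid sequence")
    x = np.asarray(lengths, dtype=float)
    w = np.asarray(weights, dtype=float)
    mean = float(np.average(x, weights=w))
    sd = float(math.sqrt(np.average((x - mean) ** 2, weights=w)))
    return LengthFit(mean=mean, sd=sd, n=len(lengths))


# ---------------------------------------------------------------------------
# Report writers


def write_spectrum_tsv(spectrum: CardinalitySpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("cardinality\tn_sequences\n")
        for k in sorted(spectrum.f):
            fh.write(f"{k}\t{spectrum.f[k]}\n")


def write_report_json(path, *, diversity: DiversityEstimate | None = None,
                      length_fit: LengthFit | None = None,
                      filter_report: dict | None = None) -> None:
    payload: dict = {}
    if diversity is not None:
        payload["diversity"] = diversity.to_json()
    if length_fit is not None:
        payload["length_fit"] = {"mean": length_fit.mean, "sd": length_fit.sd,
                                 "n": length_fit.n}
    if filter_report is not None:
        payload["full_length_filter"] = filter_report
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
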