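"""Greedy LD clumping of genome-wide-significant SNPs.

Instruments for Mendelian randomization must be approximately independent;
clumping enforces this by repeatedly keeping the remaining SNP with the
lowest p-value and discarding every other SNP on the same chromosome within
a window of it whose squared correlation (r²) with it exceeds a threshold.
Defaults follow stringent MR practice: r² < 0.01 within 1 Mb, genome-wide
significance p < 5e-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .summary_data import SnpAssociation

logger = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.01
DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_P_THRESHOLD = 5e-8


@dataclass
class LdMatrix:
    """Squared-correlation matrix over an ordered set of rsids.

    Symmetric, unit diagonal, entries in [0, 1]. Pairs not covered by the
    matrix are reported as missing (``None``) by :meth:`r2_between`.
    """

    rsids: list[str]
    r2: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise ValidationError(
                f"LD matrix shape {self.r2.shape} does not match {k} rsids"
            )
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValidationError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValidationError("LD matrix diagonal must be exactly 1")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise ValidationError("LD r² entries must lie in [0, 1]")
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def r2_between(self, a: str, b: str) -> float | None:
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str, float]], rsids: Sequence[str] | None = None
    ) -> "LdMatrix":
        """Build from long-format (rsid_a, rsid_b, r2) triples; absent pairs are 0."""
        pairs = list(pairs)
        if rsids is None:
            seen: dict[str, None] = {}
            for a, b, _ in pairs:
                seen.setdefault(a)
                seen.setdefault(b)
            rsids = list(seen)
        idx = {r: i for i, r in enumerate(rsids)}
        mat = np.eye(len(rsids))
        for a, b, r2 in pairs:
            mat[idx[a], idx[b]] = r2
            mat[idx[b], idx[a]] = r2
        return cls(list(rsids), mat)


def read_ld_matrix(path) -> LdMatrix:
    """Read an LD matrix from TSV: square (rsid header row and column) or
    long format with columns rsid_a, rsid_b, r2."""
    df = pd.read_csv(path, sep="\t")
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["rsid_a", "rsid_b", "r2"]:
        triples = [
            (str(a), str(b), float(r)) for a, b, r in df.itertuples(index=False)
        ]
        return LdMatrix.from_pairs(triples)
    rsids = [str(r) for r in df.iloc[:, 0]]
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    header = [str(c) for c in df.columns[1:]]
    if header != rsids:
        raise ValidationError("square LD matrix header row and rsid column disagree")
    return LdMatrix(rsids, mat)


def write_ld_matrix(ld: LdMatrix, path) -> None:
    df = pd.DataFrame(ld.r2, columns=ld.rsids)
    df.insert(0, "rsid", ld.rsids)
    df.to_csv(path, sep="\t", index=False)


def _chrom_key(chrom: str):
    try:
        return (0, int(chrom), chrom)
    except ValueError:
        return (1, 0, chrom)


def clump(
    snps: Sequence[SnpAssociation],
    ld: LdMatrix,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_bp: int = DEFAULT_WINDOW_BP,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    missing_ld: str = "zero",
) -> list[SnpAssociation]:
    """Greedy clump: keep lowest-p SNPs, discard correlated neighbours.

    A discarded SNP is one on the same chromosome as an already-kept SNP,
    within ``window_bp`` of it (inclusive), with r² ≥ ``r2_threshold``
    against it.  SNPs with p > ``p_threshold`` never enter.  Ties on p-value
    break by (chromosome, position, rsid) for determinism.  Pairs inside the
    window but absent from ``ld`` are treated as r²=0 with a warning
    (``missing_ld="zero"``) or raise (``missing_ld="error"``).

    Returns the retained SNPs sorted by chromosome then position.
    """
    if missing_ld not in ("zero", "error"):
        raise ConfigurationError(f"missing_ld must be 'zero' or 'error', got {missing_ld!r}")
    for s in snps:
        if s.position is None:
            raise ValidationError(f"{s.rsid}: missing position, cannot clump")

    candidates = sorted(
        (s for s in snps if s.pval <= p_threshold),
        key=lambda s: (s.pval, _chrom_key(s.chromosome), s.position, s.rsid),
    )
    kept: list[SnpAssociation] = []
    remaining = candidates
    while remaining:
        index = remaining[0]
        kept.append(index)
        survivors = []
        for s in remaining[1:]:
            if s.chromosome == index.chromosome and abs(s.position - index.position) <= window_bp:
                r2 = ld.r2_between(index.rsid, s.rsid)
                if r2 is None:
                    if missing_ld == "error":
                        raise ConfigurationError(
                            f"no LD entry for in-window pair ({index.rsid}, {s.rsid})"
                        )
                    logger.warning(
                        "no LD entry for in-window pair (%s, %s); assuming r²=0",
                        index.rsid,
                        s.rsid,
                    )
                    r2 = 0.0
                if r2 >= r2_threshold:
                    continue
            survivors.append(s)
        remaining = survivors
    return sorted(kept, key=lambda s: (_chrom_key(s.chromosome), s.position, s.rsid))
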