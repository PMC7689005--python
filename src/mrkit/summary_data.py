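"""GWAS summary-statistics I/O and two-sample allele harmonization.

A summary-statistics table has one row per SNP with the variant identity
(rsid, chromosome, position, effect and other allele), the effect-allele
frequency, and the association estimate (beta in SD-of-trait units, its
standard error, p-value, sample size).  Two-sample Mendelian randomization
needs the exposure and outcome effects of each instrument expressed with
respect to the *same* effect allele; :func:`harmonize_pair` performs that
alignment, flipping effect signs for swapped alleles, complementing
strand-flipped records, and resolving palindromic (A/T, C/G) variants by
allele frequency where unambiguous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, HarmonizationError, ValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default column headers of the TSV dialect read and written by this module.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "rsid": "SNP",
    "chromosome": "CHR",
    "position": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

#: Default ambiguity band half-width for palindromic SNPs: frequencies inside
#: [limit, 1-limit] are too close to 0.5 to infer strand.
DEFAULT_PALINDROME_EAF_LIMIT = 0.42

_RESULTS_TABLE_COLUMNS = {"method", "beta", "se", "pval"}


@dataclass
class SnpAssociation:
    """One SNP's association with one trait in one GWAS.

    ``beta`` is the per-effect-allele change in the trait, in SD units;
    ``se`` its standard error.  ``eaf`` and ``n`` may be ``None`` (missing).
    """

    rsid: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        self.chromosome = str(self.chromosome)
        self.position = int(self.position)
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: invalid effect allele {self.effect_allele!r}"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: invalid other allele {self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.rsid}: effect and other allele are both {self.effect_allele}"
            )
        if not self.se > 0:
            raise ValidationError(f"{self.rsid}: standard error must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.rsid}: p-value must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(
                f"{self.rsid}: effect-allele frequency must be in (0, 1), got {self.eaf}"
            )
        if self.n is not None:
            self.n = int(self.n)
            if self.n <= 0:
                raise ValidationError(f"{self.rsid}: sample size must be positive, got {self.n}")

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome effects of one SNP aligned to a shared effect allele.

    ``action_taken`` records what harmonization did: ``kept`` (alleles already
    matched, possibly after strand complementing), ``flipped`` (outcome beta
    negated because its alleles were swapped), ``frequency-resolved``
    (palindromic SNP oriented by allele frequency), or ``dropped``
    (irreconcilable or ambiguous; never used in estimation).
    """

    rsid: str
    effect_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None
    eaf_outcome: float | None
    palindromic: bool
    action_taken: str

    @property
    def usable(self) -> bool:
        return self.action_taken != "dropped"

    @property
    def wald_weight(self) -> float:
        """Inverse-variance weight of this instrument's Wald ratio."""
        return (self.beta_exposure / self.se_outcome) ** 2


@dataclass(frozen=True)
class TraitMeta:
    """Reporting metadata: one SD of the trait expressed in natural units."""

    trait_name: str
    sd_value: float
    sd_unit: str

    def __post_init__(self) -> None:
        if not self.sd_value > 0:
            raise ValidationError(f"{self.trait_name}: SD must be positive")

    def to_natural(self, beta_sd: float) -> float:
        """Convert an effect in SD units to natural units."""
        return beta_sd * self.sd_value


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    pair = {a1.upper(), a2.upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def _invert_column_map(column_map: Mapping[str, str] | None) -> dict[str, str]:
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(
                f"unknown field(s) in column_map: {sorted(unknown)}; "
                f"valid fields are {sorted(DEFAULT_COLUMNS)}"
            )
        cmap.update(column_map)
    return cmap


def read_summary_stats(
    path, column_map: Mapping[str, str] | None = None
) -> list[SnpAssociation]:
    """Read a tab-separated GWAS summary-statistics table.

    ``column_map`` maps field names (``rsid``, ``beta``, ...) to the headers
    used in the file; unmapped fields use :data:`DEFAULT_COLUMNS`.  Missing
    values are encoded as ``NA`` and allowed only for ``eaf`` and ``n``.
    Duplicated rsids keep the lowest-p-value row (lead-SNP semantics) with a
    logged warning.  Every row is validated; the first invalid row raises
    :class:`~mrkit.errors.ValidationError` naming its rsid.
    """
    cmap = _invert_column_map(column_map)
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False
    )
    if _RESULTS_TABLE_COLUMNS.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: this looks like an mrkit results table "
            "(columns include method/beta/se/pval), not a GWAS summary-statistics file"
        )
    missing = [h for h in cmap.values() if h not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path}: missing mandatory column(s) {missing}; present: {list(df.columns)}"
        )

    records: list[SnpAssociation] = []
    for _, row in df.iterrows():
        def opt(field: str) -> str | None:
            v = row[cmap[field]]
            return None if pd.isna(v) else v

        eaf = opt("eaf")
        n = opt("n")
        records.append(
            SnpAssociation(
                rsid=row[cmap["rsid"]],
                chromosome=row[cmap["chromosome"]],
                position=int(row[cmap["position"]]),
                effect_allele=row[cmap["effect_allele"]],
                other_allele=row[cmap["other_allele"]],
                eaf=None if eaf is None else float(eaf),
                beta=float(row[cmap["beta"]]),
                se=float(row[cmap["se"]]),
                pval=float(row[cmap["pval"]]),
                n=None if n is None else int(float(n)),
            )
        )
    return deduplicate(records)


def deduplicate(records: Sequence[SnpAssociation]) -> list[SnpAssociation]:
    """Keep the lowest-p-value row per rsid, preserving first-seen order."""
    best: dict[str, SnpAssociation] = {}
    order: list[str] = []
    for rec in records:
        if rec.rsid not in best:
            best[rec.rsid] = rec
            order.append(rec.rsid)
        else:
            logger.warning(
                "duplicated rsid %s: keeping lowest p-value row", rec.rsid
            )
            if rec.pval < best[rec.rsid].pval:
                best[rec.rsid] = rec
    return [best[r] for r in order]


def write_summary_stats(
    records: Iterable[SnpAssociation], path, column_map: Mapping[str, str] | None = None
) -> None:
    """Write records as the tab-separated dialect :func:`read_summary_stats` reads.

    Floats are written with ``repr`` so a write/read round trip reproduces
    every numeric field bit-exactly.
    """
    cmap = _invert_column_map(column_map)
    fields = list(DEFAULT_COLUMNS)

    def fmt(value) -> str:
        if value is None:
            return "NA"
        if isinstance(value, float):
            return repr(value)
        return str(value)

    with open(path, "w") as fh:
        fh.write("\t".join(cmap[f] for f in fields) + "\n")
        for rec in records:
            fh.write("\t".join(fmt(getattr(rec, f)) for f in fields) + "\n")


def records_to_frame(records: Sequence[SnpAssociation]) -> pd.DataFrame:
    """Tabular view of a record list (one row per SNP, field names as columns)."""
    return pd.DataFrame([vars(r) for r in records])


def _ambiguous_eaf(eaf: float, limit: float) -> bool:
    return limit <= eaf <= 1 - limit


def _harmonize_one(
    exp: SnpAssociation, out: SnpAssociation, limit: float
) -> HarmonizedInstrument:
    ea, oa = exp.effect_allele, exp.other_allele

    def build(beta_out, eaf_out, action):
        return HarmonizedInstrument(
            rsid=exp.rsid,
            effect_allele=ea,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=beta_out,
            se_outcome=out.se,
            eaf_exposure=exp.eaf,
            eaf_outcome=eaf_out,
            palindromic=exp.palindromic,
            action_taken=action,
        )

    if exp.palindromic:
        # Strand is ambiguous: the complement of an A/T or C/G pair is the
        # same pair, so orientation must come from allele frequencies.
        if {out.effect_allele, out.other_allele} != {ea, oa}:
            return build(out.beta, out.eaf, "dropped")
        swapped = out.effect_allele == oa
        beta_out = -out.beta if swapped else out.beta
        eaf_out = None if out.eaf is None else (1 - out.eaf if swapped else out.eaf)
        if exp.eaf is None or eaf_out is None:
            return build(beta_out, eaf_out, "dropped")
        if _ambiguous_eaf(exp.eaf, limit) or _ambiguous_eaf(eaf_out, limit):
            return build(beta_out, eaf_out, "dropped")
        if (exp.eaf < 0.5) != (eaf_out < 0.5):
            # Frequencies disagree on orientation: conservative drop.
            return build(beta_out, eaf_out, "dropped")
        return build(beta_out, eaf_out, "frequency-resolved")

    for oea, ooa, complemented in (
        (out.effect_allele, out.other_allele, False),
        (COMPLEMENT[out.effect_allele], COMPLEMENT[out.other_allele], True),
    ):
        if (oea, ooa) == (ea, oa):
            return build(out.beta, out.eaf, "kept")
        if (oea, ooa) == (oa, ea):
            eaf_out = None if out.eaf is None else 1 - out.eaf
            return build(-out.beta, eaf_out, "flipped")
    return build(out.beta, out.eaf, "dropped")


def harmonize_pair(
    exposure: Sequence[SnpAssociation],
    outcome: Sequence[SnpAssociation],
    palindrome_eaf_limit: float = DEFAULT_PALINDROME_EAF_LIMIT,
) -> list[HarmonizedInstrument]:
    """Align outcome effects onto the exposure's effect alleles, rsid by rsid.

    Only rsids present in both tables are used (no proxy lookup).  Swapped
    alleles negate the outcome beta and reflect its frequency; strand flips
    on non-palindromic SNPs are resolved by complementing; palindromic SNPs
    are kept only when both frequencies fall on the same side of 0.5 and
    outside the ambiguity band ``[limit, 1-limit]``.  Dropped instruments are
    returned with ``action_taken="dropped"`` for reporting but must never
    enter estimation.

    Raises :class:`~mrkit.errors.HarmonizationError` when no rsid is shared,
    or when every shared SNP was dropped.
    """
    if not 0 < palindrome_eaf_limit < 0.5:
        raise ConfigurationError(
            f"palindrome_eaf_limit must be in (0, 0.5), got {palindrome_eaf_limit}"
        )
    by_rsid = {r.rsid: r for r in outcome}
    shared = [e for e in exposure if e.rsid in by_rsid]
    if not shared:
        raise HarmonizationError(
            "no shared rsids between exposure and outcome tables"
        )
    insts = [_harmonize_one(e, by_rsid[e.rsid], palindrome_eaf_limit) for e in shared]
    for inst in insts:
        if inst.action_taken == "dropped":
            logger.warning("harmonization dropped %s", inst.rsid)
    if not any(i.usable for i in insts):
        raise HarmonizationError(
            f"all {len(insts)} shared SNPs were dropped in harmonization "
            "(irreconcilable alleles or ambiguous palindromes)"
        )
    return insts


def usable_instruments(
    insts: Iterable[HarmonizedInstrument],
) -> list[HarmonizedInstrument]:
    """Filter out dropped instruments (the only ones allowed in estimation)."""
    return [i for i in insts if i.usable]


def instruments_to_associations(
    insts: Iterable[HarmonizedInstrument], which: str = "exposure"
) -> list[SnpAssociation]:
    """Project harmonized instruments back to per-study association records.

    Positions/chromosomes are not carried by HarmonizedInstrument, so the
    projection uses placeholder coordinates; intended for estimator utilities
    that only need beta/se/eaf.
    """
    out = []
    for i, inst in enumerate(insts):
        beta = inst.beta_exposure if which == "exposure" else inst.beta_outcome
        se = inst.se_exposure if which == "exposure" else inst.se_outcome
        eaf = inst.eaf_exposure if which == "exposure" else inst.eaf_outcome
        z = beta / se
        pval = max(min(2 * 0.5 * math.erfc(abs(z) / math.sqrt(2)), 1.0), 5e-324)
        other = next(a for a in "ACGT" if a != inst.effect_allele)
        out.append(
            SnpAssociation(
                rsid=inst.rsid,
                chromosome="0",
                position=i + 1,
                effect_allele=inst.effect_allele,
                other_allele=other,
                eaf=eaf,
                beta=beta,
                se=se,
                pval=pval,
            )
        )
    return out


def flip_exposure(inst: HarmonizedInstrument) -> HarmonizedInstrument:
    """Re-express an instrument with respect to the other exposure allele.

    Negates both betas and reflects both frequencies; the Wald ratio is
    invariant under this operation.
    """
    other = next(
        a for a in "ACGT"
        if a != inst.effect_allele
    )
    return replace(
        inst,
        effect_allele=other,
        beta_exposure=-inst.beta_exposure,
        beta_outcome=-inst.beta_outcome,
        eaf_exposure=None if inst.eaf_exposure is None else 1 - inst.eaf_exposure,
        eaf_outcome=None if inst.eaf_outcome is None else 1 - inst.eaf_outcome,
    )
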