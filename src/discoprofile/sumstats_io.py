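"""Reading, validation, harmonization and LD utilities for GWAS summary statistics.

Summary statistics live in pandas DataFrames with the canonical columns
``snp_id, chrom, pos, ea, oa, eaf, beta, se, p, n`` (optionally ``n_cases``,
``n_controls``).  A :class:`ReferencePanel` wraps per-individual allele dosages
used for LD (r^2) computation, clumping and proxy search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: palindromic allele pairs are strand-ambiguous
PALINDROMES = {frozenset(("A", "T")), frozenset(("C", "G"))}

REQUIRED_COLUMNS = ("snp_id", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n")
OPTIONAL_COLUMNS = ("n_cases", "n_controls")

#: decimal precision used by write_sumstats; read->write->read round-trips exactly
WRITE_PRECISION = 12


class ConfigurationError(ValueError):
    """A required column or parameter is missing or inconsistent."""


class EmptyInputError(ValueError):
    """The input file or table holds no usable rows."""


class DegenerateInputError(ValueError):
    """An input is structurally valid but statistically degenerate (e.g. zero variance)."""


class LookupError_(KeyError):
    """A requested SNP is not present in the panel."""


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP-trait association: the atom of all summary-level stages."""

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: float
    n_cases: Optional[float] = None
    n_controls: Optional[float] = None

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def is_palindromic(self) -> bool:
        return self.alleles in PALINDROMES


@dataclass(frozen=True)
class HarmonizedPair:
    """Two studies' effects at one SNP expressed per copy of a shared effect allele."""

    snp_id: str
    aligned_effect_allele: Optional[str] = None
    other_allele: Optional[str] = None
    beta_a: Optional[float] = None
    se_a: Optional[float] = None
    p_a: Optional[float] = None
    eaf: Optional[float] = None
    beta_b: Optional[float] = None
    se_b: Optional[float] = None
    p_b: Optional[float] = None
    drop_reason: Optional[str] = None  # palindromic_ambiguous | allele_mismatch | not_biallelic

    @property
    def dropped(self) -> bool:
        return self.drop_reason is not None


@dataclass
class ReferencePanel:
    """Individual x SNP dosage matrix (values in [0, 2]) plus SNP metadata.

    ``meta`` columns: snp_id, chrom, pos, ref, alt; row order matches the
    columns of ``dosages``.
    """

    meta: pd.DataFrame
    dosages: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.meta):
            raise ConfigurationError(
                f"dosage matrix has {self.dosages.shape[1]} columns for "
                f"{len(self.meta)} SNPs"
            )
        self._index = {s: i for i, s in enumerate(self.meta["snp_id"])}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def column(self, snp_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[snp_id]]
        except KeyError:
            raise LookupError_(f"SNP {snp_id!r} not in reference panel") from None

    def position(self, snp_id: str) -> tuple[str, int]:
        try:
            i = self._index[snp_id]
        except KeyError:
            raise LookupError_(f"SNP {snp_id!r} not in reference panel") from None
        row = self.meta.iloc[i]
        return str(row["chrom"]), int(row["pos"])

    def maf(self, snp_id: str) -> float:
        f = float(np.mean(self.column(snp_id))) / 2.0
        return min(f, 1.0 - f)

    @classmethod
    def from_dosage_tsv(cls, path) -> "ReferencePanel":
        """Load a dosage-matrix TSV: first column individual id, then one column
        per SNP named ``snp_id:chrom:pos:ref:alt``."""
        df = pd.read_csv(path, sep="\t")
        snp_cols = df.columns[1:]
        meta = pd.DataFrame(
            [c.split(":") for c in snp_cols],
            columns=["snp_id", "chrom", "pos", "ref", "alt"],
        )
        meta["pos"] = meta["pos"].astype(int)
        return cls(meta=meta, dosages=df[snp_cols].to_numpy(dtype=float))

    def to_dosage_tsv(self, path) -> None:
        cols = [
            f"{r.snp_id}:{r.chrom}:{r.pos}:{r.ref}:{r.alt}"
            for r in self.meta.itertuples()
        ]
        out = pd.DataFrame(self.dosages, columns=cols)
        out.insert(0, "iid", [f"I{i:06d}" for i in range(len(out))])
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_vcf(cls, path) -> "ReferencePanel":
        """Load biallelic records from a VCF, using DS when present else GT."""
        from cyvcf2 import VCF

        ids, chroms, poss, refs, alts, cols = [], [], [], [], [], []
        for v in VCF(str(path)):
            if len(v.ALT) != 1:
                continue
            ids.append(v.ID or f"{v.CHROM}:{v.POS}")
            chroms.append(str(v.CHROM))
            poss.append(int(v.POS))
            refs.append(v.REF)
            alts.append(v.ALT[0])
            try:
                ds = np.asarray(v.format("DS"), dtype=float).ravel()
            except (KeyError, TypeError, ValueError):
                gt = np.asarray(v.gt_types, dtype=float)  # 0,1,3 -> dosage; 2=unknown
                ds = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
            cols.append(ds)
        if not cols:
            raise EmptyInputError(f"no biallelic records in {path}")
        meta = pd.DataFrame(
            {"snp_id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
        )
        return cls(meta=meta, dosages=np.column_stack(cols))


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the record invariants; return (clean frame, n dropped)."""
    n0 = len(df)
    for col in ("pos", "eaf", "beta", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    alleles_ok = (
        df["ea"].astype(str).str.upper().isin(BASES)
        & df["oa"].astype(str).str.upper().isin(BASES)
        & (df["ea"].astype(str).str.upper() != df["oa"].astype(str).str.upper())
    )
    keep = (
        alleles_ok
        & df["se"].gt(0)
        & df["p"].gt(0)
        & df["p"].le(1)
        & df["eaf"].gt(0)
        & df["eaf"].lt(1)
        & df["n"].gt(0)
        & df[["pos", "beta"]].notna().all(axis=1)
    )
    if "n_cases" in df.columns and "n_controls" in df.columns:
        both = df["n_cases"].notna() & df["n_controls"].notna()
        keep &= ~both | np.isclose(
            df["n_cases"].fillna(0) + df["n_controls"].fillna(0), df["n"]
        )
    out = df.loc[keep].copy()
    out["ea"] = out["ea"].str.upper()
    out["oa"] = out["oa"].str.upper()
    out["pos"] = out["pos"].astype(int)
    return out.reset_index(drop=True), n0 - len(out)


def read_sumstats(
    path, column_map: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Read a delimited summary-statistics table into canonical columns.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"p": "P_value"}``; unmapped canonical names are looked up verbatim.
    Rows violating the record invariants are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise EmptyInputError(f"{path} holds no data rows")
    column_map = dict(column_map or {})
    rename = {}
    for canon in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in df.columns:
            rename[src] = canon
        elif canon in REQUIRED_COLUMNS:
            raise ConfigurationError(
                f"required column {canon!r} (file column {src!r}) missing from {path}"
            )
    df = df.rename(columns=rename)[list(rename.values())]
    df, n_dropped = _validate_frame(df)
    if n_dropped:
        logger.info("read_sumstats: dropped %d invalid rows from %s", n_dropped, path)
    df.attrs["n_dropped"] = n_dropped
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write canonical summary statistics as TSV at a fixed decimal precision."""
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{WRITE_PRECISION}g")


def records_from_frame(df: pd.DataFrame) -> list[SumStatRecord]:
    recs = []
    for r in df.itertuples():
        recs.append(
            SumStatRecord(
                snp_id=r.snp_id,
                chrom=str(r.chrom),
                pos=int(r.pos),
                effect_allele=r.ea,
                other_allele=r.oa,
                eaf=float(r.eaf),
                beta=float(r.beta),
                se=float(r.se),
                p=float(r.p),
                n=float(r.n),
                n_cases=getattr(r, "n_cases", None),
                n_controls=getattr(r, "n_controls", None),
            )
        )
    return recs


def harmonize(
    rec_a: SumStatRecord,
    rec_b: SumStatRecord,
    palindrome_maf_cut: float = 0.30,
) -> HarmonizedPair:
    """Express both studies' effects per copy of study A's effect allele.

    If B's effect allele equals A's other allele the sign of ``beta_b`` is
    flipped (and its frequency complemented).  Palindromic SNPs (A/T or C/G)
    with MAF above ``palindrome_maf_cut`` are strand-ambiguous and dropped;
    non-matching allele sets are dropped.  No strand flips are attempted.
    MAF for the palindrome rule comes from the first record.
    """
    if rec_a.snp_id != rec_b.snp_id:
        raise ConfigurationError("records to harmonize must share snp_id")
    if not (rec_a.alleles <= BASES and rec_b.alleles <= BASES):
        return HarmonizedPair(rec_a.snp_id, drop_reason="not_biallelic")
    if rec_a.is_palindromic and rec_a.maf > palindrome_maf_cut:
        return HarmonizedPair(rec_a.snp_id, drop_reason="palindromic_ambiguous")
    if rec_b.alleles != rec_a.alleles:
        return HarmonizedPair(rec_a.snp_id, drop_reason="allele_mismatch")
    if rec_b.effect_allele == rec_a.effect_allele:
        beta_b, eaf_b = rec_b.beta, rec_b.eaf
    else:  # B reported on A's other allele
        beta_b, eaf_b = -rec_b.beta, 1.0 - rec_b.eaf
    eaf = rec_a.eaf if not np.isnan(rec_a.eaf) else eaf_b
    return HarmonizedPair(
        snp_id=rec_a.snp_id,
        aligned_effect_allele=rec_a.effect_allele,
        other_allele=rec_a.other_allele,
        beta_a=rec_a.beta,
        se_a=rec_a.se,
        p_a=rec_a.p,
        eaf=eaf,
        beta_b=beta_b,
        se_b=rec_b.se,
        p_b=rec_b.p,
    )


def ld_r2(panel: ReferencePanel, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation of dosages (symmetric, recode-invariant)."""
    x = panel.column(snp_i)
    y = panel.column(snp_j)
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateInputError("zero-variance SNP in ld_r2")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def dosage_correlation_sign(panel: ReferencePanel, snp_i: str, snp_j: str) -> int:
    """Sign of the dosage correlation, used to align proxy effect alleles."""
    r = np.corrcoef(panel.column(snp_i), panel.column(snp_j))[0, 1]
    return 1 if r >= 0 else -1


def find_proxy(
    panel: ReferencePanel,
    target: str,
    candidates: Iterable[str],
    r2_min: float = 0.5,
    window_bp: int = 500_000,
) -> Optional[str]:
    """Best LD proxy for ``target`` among ``candidates`` within the window.

    Returns the candidate with maximal r^2 if r^2 >= ``r2_min``, else None.
    Ties are broken by smaller base-pair distance, then lexicographic id.
    The window is symmetric and inclusive: |pos_t - pos_c| <= window_bp.
    """
    chrom_t, pos_t = panel.position(target)
    best = None  # (-r2, distance, id)
    for cand in sorted(set(candidates)):
        if cand == target or cand not in panel:
            continue
        chrom_c, pos_c = panel.position(cand)
        if chrom_c != chrom_t or abs(pos_c - pos_t) > window_bp:
            continue
        try:
            r2 = ld_r2(panel, target, cand)
        except DegenerateInputError:
            continue
        key = (-round(r2, 12), abs(pos_c - pos_t), cand)
        if best is None or key < best:
            best = key
    if best is not None and -best[0] >= r2_min:
        return best[2]
    return None
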