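"""Marker-table I/O, per-subpool frequencies, and marker quality control.

The experiment sequences nine DNA pools per marker panel: three replicate
subpools of 30 diploid segregants (60 chromosomes) for each of the
growth-selected tail, the survival-selected tail, and the unselected F6
control.  All downstream statistics are expressed as the frequency of the
wild-parent (YE-531) allele.

On disk a marker panel is a tab-separated table with one row per marker::

    chrom  pos  allele_s288c  allele_ye531  cnt_<cat>_<j>_ye531  cnt_<cat>_<j>_other ...

for cat in {growth, survival, control} and subpool j in {1, 2, 3}; '.'
marks a missing count.  Columns are matched by name, not position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, DuplicateMarkerError, FormatError,
                     UndefinedResultError)

log = logging.getLogger(__name__)

CATEGORIES = ("growth", "survival", "control")
#: category -> k code used in the statistical notation (1, 2, 3)
CATEGORY_CODES = {"growth": 1, "survival": 2, "control": 3}
SUBPOOLS = (1, 2, 3)

KEY_COLUMNS = ["chrom", "pos", "allele_s288c", "allele_ye531"]


@dataclass(frozen=True)
class PoolDesign:
    """The pooling layout: 3 replicate subpools of 30 diploids per category."""

    categories: tuple[str, ...] = CATEGORIES
    subpools_per_category: int = 3
    individuals_per_subpool: int = 30

    @property
    def chromosomes_per_subpool(self) -> int:
        return 2 * self.individuals_per_subpool


def count_columns(design: PoolDesign = PoolDesign()) -> list[str]:
    cols = []
    for cat in design.categories:
        for j in range(1, design.subpools_per_category + 1):
            cols += [f"cnt_{cat}_{j}_ye531", f"cnt_{cat}_{j}_other"]
    return cols


@dataclass
class FrequencyMatrix:
    """YE-531 allele frequencies per marker and (category, subpool) column.

    ``values`` is a DataFrame indexed like the source marker table, with a
    (category, subpool) MultiIndex on the columns; ``stage`` records
    whether the values are raw ratios or LOESS-smoothed.
    """

    values: pd.DataFrame
    stage: str = "raw"
    markers: pd.DataFrame | None = None

    def category(self, cat: str) -> pd.DataFrame:
        if cat not in CATEGORIES:
            raise ConfigurationError(f"unknown category {cat!r}")
        return self.values[cat]


def read_marker_table(path, design: PoolDesign = PoolDesign()) -> pd.DataFrame:
    """Read and validate a tab-separated marker table.

    Returns a DataFrame sorted by (chrom, pos) with nullable-integer count
    columns ('.' -> missing).  Raises :class:`FormatError` naming the
    offending rows for missing columns or negative counts, and
    :class:`DuplicateMarkerError` for repeated (chrom, pos).
    """
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"chrom": str})
    required = KEY_COLUMNS + count_columns(design)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df[required].copy()

    if df["pos"].isna().any() or (df["pos"] < 1).any():
        bad = df.index[df["pos"].isna() | (df["pos"] < 1)] + 2  # 1-based + header
        raise FormatError(f"invalid pos at file line(s) {list(bad)}")
    df["pos"] = df["pos"].astype(np.int64)

    cnt_cols = count_columns(design)
    for c in cnt_cols:
        col = pd.to_numeric(df[c], errors="coerce")
        bad_parse = df[c].notna() & col.isna()
        if bad_parse.any():
            raise FormatError(
                f"non-numeric count in column {c} at file line(s) "
                f"{list(bad_parse[bad_parse].index + 2)}")
        if (col < 0).any():
            raise FormatError(
                f"negative count in column {c} at file line(s) "
                f"{list(col.index[col < 0] + 2)}")
        df[c] = col.round().astype("Int64")

    dup = df.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["chrom", "pos"]].drop_duplicates()
        raise DuplicateMarkerError(
            "duplicate (chrom, pos): "
            + ", ".join(f"{r.chrom}:{r.pos}" for r in pairs.itertuples()))

    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return df


def write_marker_table(df: pd.DataFrame, path,
                       design: PoolDesign = PoolDesign()) -> None:
    """Write a marker table in the on-disk format (missing counts as '.')."""
    cols = KEY_COLUMNS + count_columns(design)
    df[cols].to_csv(path, sep="\t", index=False, na_rep=".")


def frequencies(df: pd.DataFrame,
                design: PoolDesign = PoolDesign()) -> FrequencyMatrix:
    """Raw YE-531 allele frequencies; NaN where a subpool has zero depth."""
    data = {}
    for cat in design.categories:
        for j in range(1, design.subpools_per_category + 1):
            ye = df[f"cnt_{cat}_{j}_ye531"].astype(float)
            ot = df[f"cnt_{cat}_{j}_other"].astype(float)
            tot = ye + ot
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(tot > 0, ye / tot, np.nan)
            data[(cat, j)] = f
    values = pd.DataFrame(data, index=df.index)
    values.columns = pd.MultiIndex.from_tuples(values.columns,
                                               names=["category", "subpool"])
    return FrequencyMatrix(values=values, stage="raw", markers=df)


def read_vcf_pools(path, sample_map: Mapping[str, tuple[str, int]],
                   ye531_alleles: Mapping[tuple[str, int], str],
                   design: PoolDesign = PoolDesign()) -> tuple[pd.DataFrame, int]:
    """Build a marker table from a VCF with per-sample allele depths (AD).

    ``sample_map`` maps VCF sample names to (category, subpool); every
    mapped sample must exist in the file.  ``ye531_alleles`` gives the
    wild-parent allele per (chrom, pos) site; REF/ALT are assigned to the
    YE-531 vs other count accordingly.  Multi-allelic records are skipped;
    the skip count is returned alongside the table.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ConfigurationError(
            "VCF input requires the cyvcf2 package (install ailmap[vcf])"
        ) from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in sample_map if s not in samples]
    if missing:
        raise ConfigurationError(
            f"sample(s) in map absent from VCF: {', '.join(missing)}")
    sample_idx = {s: samples.index(s) for s in sample_map}

    rows = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        key = (rec.CHROM, rec.POS)
        ye_allele = ye531_alleles.get(key)
        if ye_allele is None:
            skipped += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if ye_allele == alt:
            s288c_allele, ye_idx = ref, 1
        elif ye_allele == ref:
            s288c_allele, ye_idx = alt, 0
        else:
            skipped += 1
            continue
        ad = rec.format("AD")
        row: dict = {"chrom": rec.CHROM, "pos": rec.POS,
                     "allele_s288c": s288c_allele, "allele_ye531": ye_allele}
        for s, (cat, j) in sample_map.items():
            depths = ad[sample_idx[s]]
            ye_cnt = int(depths[ye_idx])
            ot_cnt = int(depths[1 - ye_idx])
            row[f"cnt_{cat}_{j}_ye531"] = max(ye_cnt, 0)
            row[f"cnt_{cat}_{j}_other"] = max(ot_cnt, 0)
        rows.append(row)
    if skipped:
        log.info("skipped %d VCF records (multi-allelic or unannotated)", skipped)

    if not rows:
        df = pd.DataFrame(columns=KEY_COLUMNS + count_columns(design))
    else:
        df = pd.DataFrame(rows)
    buf = StringIO()
    write_marker_table(df, buf, design)
    buf.seek(0)
    return read_marker_table(buf, design), skipped


# ---------------------------------------------------------------------------
# Quality control


#: rule names in first-failure reporting order
QC_RULES = ("caller_discordant", "parent_impure", "dual_ref_mismatch", "low_maf")


@dataclass
class QCReport:
    """Removal bookkeeping for one filtering pass."""

    n_input: int
    n_passing: int
    first_failure: dict = field(default_factory=dict)
    per_rule: dict = field(default_factory=dict)
    flagged_parent_low_coverage: int = 0

    def __post_init__(self) -> None:
        assert self.n_input == self.n_passing + sum(self.first_failure.values())


def filter_markers(
    df: pd.DataFrame,
    maf_min: float = 0.05,
    parent_freqs: pd.Series | None = None,
    parent_depths: pd.Series | None = None,
    parent_min_coverage: int = 10,
    dual_ref: pd.Series | None = None,
    dual_ref_tol: float = 0.01,
    caller_concordant: pd.Series | None = None,
    design: PoolDesign = PoolDesign(),
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the marker quality-control filters; return passers and a report.

    A marker is kept iff every *provided* check passes:

    * ``caller_concordant`` — boolean per marker; variant callers agreed;
    * ``parent_freqs`` — YE-531 frequency in pure YE-531 samples must be
      exactly 1 (the wild parent is haploid).  When ``parent_depths`` is
      given, markers below ``parent_min_coverage`` are only flagged, not
      removed — purity cannot be judged from a handful of reads;
    * ``dual_ref`` — a second frequency estimate (from mapping against
      the other reference genome) that must agree with the pooled control
      frequency within ``dual_ref_tol``;
    * pooled minor-allele frequency in the control pools ``>= maf_min``
      (a marker at exactly ``maf_min`` is kept).

    Optional inputs are aligned to ``df`` by (chrom, pos) via their index
    when it is a MultiIndex, else positionally.  The report counts both
    first-failure removals (in the order caller -> parent -> dual-ref ->
    MAF) and per-rule tallies.
    """
    n = len(df)
    key = pd.MultiIndex.from_frame(df[["chrom", "pos"]])

    def _aligned(s: pd.Series | None) -> pd.Series | None:
        if s is None:
            return None
        if isinstance(s.index, pd.MultiIndex):
            return s.reindex(key).reset_index(drop=True)
        return s.reset_index(drop=True)

    caller = _aligned(caller_concordant)
    pfreq = _aligned(parent_freqs)
    pdepth = _aligned(parent_depths)
    dref = _aligned(dual_ref)

    fail = pd.DataFrame(False, index=df.index, columns=list(QC_RULES))
    flagged_low_cov = 0

    if caller is not None:
        fail["caller_discordant"] = ~caller.fillna(False).astype(bool).values

    if pfreq is not None:
        impure = (pfreq != 1.0) & pfreq.notna()
        if pdepth is not None:
            low_cov = pdepth.fillna(0) < parent_min_coverage
            flagged_low_cov = int((impure & low_cov).sum())
            impure &= ~low_cov
        fail["parent_impure"] = impure.values

    # Pooled control frequency: total counts across the three control subpools.
    ye = sum(df[f"cnt_control_{j}_ye531"].fillna(0).astype(float) for j in SUBPOOLS)
    ot = sum(df[f"cnt_control_{j}_other"].fillna(0).astype(float) for j in SUBPOOLS)
    tot = ye + ot
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(tot > 0, ye / tot, np.nan)

    if dref is not None:
        diff = np.abs(dref.values.astype(float) - pooled)
        fail["dual_ref_mismatch"] = (diff > dual_ref_tol) & ~np.isnan(diff)

    maf = np.minimum(pooled, 1.0 - pooled)
    fail["low_maf"] = np.isnan(maf) | (maf < maf_min)

    any_fail = fail.any(axis=1)
    first = fail.idxmax(axis=1).where(any_fail)
    report = QCReport(
        n_input=n,
        n_passing=int((~any_fail).sum()),
        first_failure={r: int((first == r).sum()) for r in QC_RULES},
        per_rule={r: int(fail[r].sum()) for r in QC_RULES},
        flagged_parent_low_coverage=flagged_low_cov,
    )
    passing = df[~any_fail].reset_index(drop=True)
    return passing, report


def major_allele_origin(freqs: FrequencyMatrix, category: str = "control") -> dict:
    """Which parent contributes the major allele, and lost/fixed tallies.

    Works on the per-marker mean frequency across the category's three
    subpools.  Markers at exactly 0.5 are reported as ties and excluded
    from the proportions; lost = frequency 0, fixed = frequency 1 (of the
    YE-531 allele).
    """
    sub = freqs.category(category)
    mean = sub.mean(axis=1, skipna=True).dropna()
    if mean.empty:
        raise UndefinedResultError("no markers with defined frequencies")
    tied = int((mean == 0.5).sum())
    ye_major = int((mean > 0.5).sum())
    s288c_major = int((mean < 0.5).sum())
    non_tied = ye_major + s288c_major
    return {
        "n": int(mean.size),
        "ye531_major": ye_major,
        "s288c_major": s288c_major,
        "tied": tied,
        "prop_ye531_major": ye_major / non_tied if non_tied else float("nan"),
        "prop_s288c_major": s288c_major / non_tied if non_tied else float("nan"),
        "lost": int((mean == 0.0).sum()),
        "fixed": int((mean == 1.0).sum()),
    }
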