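"""Harmonized two-sample summary data: domain types, validation, I/O, merging.

The universal input of every estimator in this package is a
:class:`SummarySet`: one row per genetic variant carrying the
instrument-exposure association ``beta_exposure`` (:math:`\\hat\\gamma_j`)
with standard error ``se_exposure`` (:math:`\\sigma_{Xj}`), and the
instrument-outcome association ``beta_outcome`` (:math:`\\hat\\Gamma_j`)
with standard error ``se_outcome`` (:math:`\\sigma_{Yj}`).  The two sides
come from different GWAS samples; :func:`merge_two_samples` builds the
harmonized table from separate exposure-side and outcome-side tables.

No genomic coordinates are consumed anywhere: variants are keyed by their
identifier (typically an rsID) only, and inputs are assumed pre-pruned for
linkage disequilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, NullInstrumentError, ValidationError

__all__ = [
    "VariantRecord",
    "SummarySet",
    "read_summary_table",
    "write_summary_table",
    "merge_two_samples",
    "ratio_estimates",
    "CANONICAL_FIELDS",
]

#: Canonical field names accepted in column maps and table headers.
CANONICAL_FIELDS = (
    "variant_id",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
    "effect_allele",
    "other_allele",
    "eaf",
)

_REQUIRED = CANONICAL_FIELDS[:5]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class VariantRecord:
    """Per-variant association summaries from both samples.

    Parameters
    ----------
    variant_id : str
        Non-empty identifier, typically an rsID.
    beta_exposure, se_exposure : float
        Instrument-exposure association :math:`\\hat\\gamma_j` and its
        standard error :math:`\\sigma_{Xj} > 0`, in the exposure GWAS units.
    beta_outcome, se_outcome : float
        Instrument-outcome association :math:`\\hat\\Gamma_j` and its
        standard error :math:`\\sigma_{Yj} > 0`, in the outcome GWAS units.
    effect_allele, other_allele : str, optional
        Alleles on the exposure scale; needed only for harmonization.
    eaf : float, optional
        Effect-allele frequency in (0, 1); used to resolve palindromic
        variants when that option is enabled.
    """

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    effect_allele: str | None = None
    other_allele: str | None = None
    eaf: float | None = None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValidationError("variant_id must be non-empty")
        if not (self.se_exposure > 0):
            raise ValidationError(
                f"variant {self.variant_id!r}: se_exposure must be > 0, "
                f"got {self.se_exposure!r}"
            )
        if not (self.se_outcome > 0):
            raise ValidationError(
                f"variant {self.variant_id!r}: se_outcome must be > 0, "
                f"got {self.se_outcome!r}"
            )
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(
                f"variant {self.variant_id!r}: eaf must lie in (0, 1), got {self.eaf!r}"
            )


@dataclass(frozen=True)
class SummarySet:
    """An ordered, validated collection of :class:`VariantRecord`.

    ``meta`` carries provenance that is not part of the statistical content:
    harmonization reports from :func:`merge_two_samples`, rejected-row
    reports from :func:`read_summary_table`, or ground truth attached by the
    simulator.  It never influences any estimator.
    """

    records: tuple[VariantRecord, ...]
    exposure_label: str = "exposure"
    outcome_label: str = "outcome"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValidationError("SummarySet requires at least one variant")
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({v for v in ids if ids.count(v) > 1})
            raise ValidationError(f"duplicate variant_id values: {dupes}")
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    # -- array accessors -------------------------------------------------
    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    @property
    def beta_exposure(self) -> np.ndarray:
        return np.array([r.beta_exposure for r in self.records], dtype=float)

    @property
    def se_exposure(self) -> np.ndarray:
        return np.array([r.se_exposure for r in self.records], dtype=float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return np.array([r.beta_outcome for r in self.records], dtype=float)

    @property
    def se_outcome(self) -> np.ndarray:
        return np.array([r.se_outcome for r in self.records], dtype=float)

    # -- construction / conversion ---------------------------------------
    @classmethod
    def from_arrays(
        cls,
        beta_exposure: Sequence[float],
        se_exposure: Sequence[float],
        beta_outcome: Sequence[float],
        se_outcome: Sequence[float],
        variant_ids: Sequence[str] | None = None,
        **kwargs,
    ) -> "SummarySet":
        """Build a set from parallel arrays; ids default to ``snp_0001`` style."""
        n = len(beta_exposure)
        if variant_ids is None:
            width = max(4, len(str(n)))
            variant_ids = [f"snp_{i + 1:0{width}d}" for i in range(n)]
        records = tuple(
            VariantRecord(str(v), float(bx), float(sx), float(by), float(sy))
            for v, bx, sx, by, sy in zip(
                variant_ids, beta_exposure, se_exposure, beta_outcome, se_outcome
            )
        )
        return cls(records, **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        """One row per variant with the canonical column names, input order."""
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "beta_exposure": self.beta_exposure,
                "se_exposure": self.se_exposure,
                "beta_outcome": self.beta_outcome,
                "se_outcome": self.se_outcome,
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [r.eaf for r in self.records],
            }
        )

    def subset(self, keep: Iterable[str]) -> "SummarySet":
        """Restrict to the given variant ids, preserving order."""
        keep = set(keep)
        records = tuple(r for r in self.records if r.variant_id in keep)
        return replace(self, records=records)

    def drop_null_instruments(self) -> "SummarySet":
        """Drop variants with ``beta_exposure == 0``, warning with their ids."""
        dropped = [r.variant_id for r in self.records if r.beta_exposure == 0.0]
        if not dropped:
            return self
        warnings.warn(
            f"dropping {len(dropped)} null instrument(s) with beta_exposure == 0: "
            f"{dropped}",
            stacklevel=2,
        )
        records = tuple(r for r in self.records if r.beta_exposure != 0.0)
        meta = dict(self.meta)
        meta.setdefault("dropped_null_instruments", []).extend(dropped)
        return replace(self, records=records, meta=meta)


def _resolve_columns(
    frame_columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical field names to actual column names, validating presence."""
    column_map = dict(column_map or {})
    unknown = set(column_map) - set(CANONICAL_FIELDS)
    if unknown:
        raise ConfigurationError(
            f"unknown canonical field(s) in column map: {sorted(unknown)}; "
            f"valid fields are {list(CANONICAL_FIELDS)}"
        )
    resolved: dict[str, str] = {}
    for canon in CANONICAL_FIELDS:
        col = column_map.get(canon, canon)
        if col in frame_columns:
            resolved[canon] = col
        elif canon in _REQUIRED:
            raise ConfigurationError(
                f"required column {col!r} (canonical field {canon!r}) "
                f"not found in header {list(frame_columns)}"
            )
    return resolved


def read_summary_table(
    path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = "\t",
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
) -> SummarySet:
    """Read a delimited harmonized summary table into a :class:`SummarySet`.

    Column mapping is explicit: ``column_map`` maps canonical field names
    (``variant_id``, ``beta_exposure``, ``se_exposure``, ``beta_outcome``,
    ``se_outcome`` and the optional allele/eaf fields) to the file's column
    names; unmapped canonical names are looked up verbatim.  There is no
    header sniffing — heterogeneous GWAS export formats make silent guessing
    a correctness hazard.

    Rows with a missing required field are dropped and itemized in
    ``result.meta["rejected_rows"]``; invalid values (``se <= 0``) raise a
    :class:`~summr.exceptions.ValidationError` naming the variant.
    """
    frame = pd.read_csv(path, sep=delimiter, dtype={0: str}, float_precision="round_trip")
    resolved = _resolve_columns(frame.columns, column_map)
    rejected: list[dict] = []
    records: list[VariantRecord] = []
    for idx, row in frame.iterrows():
        values = {}
        missing = []
        for canon in _REQUIRED:
            raw = row[resolved[canon]]
            if pd.isna(raw) or (isinstance(raw, str) and not raw.strip()):
                missing.append(canon)
            else:
                values[canon] = raw
        if missing:
            rejected.append(
                {"row": int(idx), "reason": f"missing required field(s): {missing}"}
            )
            continue
        for canon in ("effect_allele", "other_allele", "eaf"):
            if canon in resolved and not pd.isna(row[resolved[canon]]):
                values[canon] = row[resolved[canon]]
        try:
            for num in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
                values[num] = float(values[num])
            if "eaf" in values:
                values["eaf"] = float(values["eaf"])
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"row {idx} (variant {values.get('variant_id')!r}): "
                f"non-numeric value in a numeric field ({exc})"
            ) from exc
        values["variant_id"] = str(values["variant_id"])
        records.append(VariantRecord(**values))
    meta = {"source": str(path)}
    if rejected:
        meta["rejected_rows"] = rejected
    return SummarySet(
        tuple(records),
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        meta=meta,
    )


def write_summary_table(data: SummarySet, path, delimiter: str = "\t") -> None:
    """Write a :class:`SummarySet` as delimited text, round-tripping floats.

    Uses shortest-repr float formatting so read → write → read preserves
    every numeric field bit-for-bit.
    """
    frame = data.to_dataframe()
    # drop all-empty optional columns for clean minimal files
    for col in ("effect_allele", "other_allele", "eaf"):
        if frame[col].isna().all():
            frame = frame.drop(columns=col)
    frame.to_csv(path, sep=delimiter, index=False, float_format=None)


# ---------------------------------------------------------------------------
# two-sample merge and allele harmonization
# ---------------------------------------------------------------------------

def _norm_allele(a) -> str | None:
    if a is None or (isinstance(a, float) and np.isnan(a)):
        return None
    s = str(a).strip().upper()
    return s or None


def _is_palindromic(effect: str, other: str) -> bool:
    return _COMPLEMENT.get(effect) == other


def _classify_alleles(
    e_eff: str, e_oth: str, o_eff: str, o_oth: str
) -> str:
    """Classify the outcome allele pair relative to the exposure pair.

    Returns one of ``same``, ``swap`` (effect/other exchanged: flip the
    outcome beta sign), ``flip`` (opposite strand, same orientation),
    ``flip_swap`` (opposite strand and exchanged), or ``mismatch``.
    """
    ce, co = _COMPLEMENT.get(o_eff), _COMPLEMENT.get(o_oth)
    if (o_eff, o_oth) == (e_eff, e_oth):
        return "same"
    if (o_eff, o_oth) == (e_oth, e_eff):
        return "swap"
    if (ce, co) == (e_eff, e_oth):
        return "flip"
    if (ce, co) == (e_oth, e_eff):
        return "flip_swap"
    return "mismatch"


def merge_two_samples(
    exposure_table: pd.DataFrame,
    outcome_table: pd.DataFrame,
    exposure_label: str = "exposure",
    outcome_label: str = "outcome",
    infer_palindromic: bool = False,
    palindromic_eaf_threshold: float = 0.42,
) -> SummarySet:
    """Inner-join exposure-side and outcome-side tables into a harmonized set.

    Each input frame carries canonical columns ``variant_id``, ``beta``,
    ``se`` and optionally ``effect_allele``, ``other_allele``, ``eaf`` for
    its own sample.  When both sides carry alleles the outcome side is
    aligned to the exposure side's effect allele: an effect/other swap
    flips the sign of the outcome beta, a strand flip relabels alleles,
    and pairs that match under neither transformation are dropped.
    Palindromic variants (A/T or G/C) are dropped by default because strand
    cannot be inferred from alleles alone; with ``infer_palindromic=True``
    they are resolved by comparing allele frequencies when both sides'
    EAFs are decisive (further than ``palindromic_eaf_threshold`` from 0.5
    ... i.e. outside (threshold, 1 - threshold)), and dropped otherwise.

    The harmonization report — one ``{variant_id, action, reason}`` entry
    per non-trivially handled variant — is stored in
    ``result.meta["harmonization_report"]``; ``result.meta["harmonization"]``
    is ``"performed"`` or ``"skipped"`` (no alleles on one or both sides).
    """
    for name, tab in (("exposure", exposure_table), ("outcome", outcome_table)):
        for col in ("variant_id", "beta", "se"):
            if col not in tab.columns:
                raise ConfigurationError(
                    f"{name} table lacks required column {col!r}"
                )
    exp = exposure_table.set_index(exposure_table["variant_id"].astype(str))
    out = outcome_table.set_index(outcome_table["variant_id"].astype(str))
    shared = [v for v in exp.index if v in set(out.index)]
    if not shared:
        raise ValidationError(
            "zero shared variants between exposure and outcome tables"
        )

    have_alleles = all(
        c in t.columns for t in (exp, out) for c in ("effect_allele", "other_allele")
    )
    report: list[dict] = []
    records: list[VariantRecord] = []
    for vid in shared:
        e, o = exp.loc[vid], out.loc[vid]
        by, sign = float(o["beta"]), 1.0
        eaf = float(e["eaf"]) if "eaf" in exp.columns and pd.notna(e.get("eaf")) else None
        e_eff = _norm_allele(e.get("effect_allele")) if have_alleles else None
        e_oth = _norm_allele(e.get("other_allele")) if have_alleles else None
        if have_alleles and e_eff and e_oth:
            o_eff = _norm_allele(o.get("effect_allele"))
            o_oth = _norm_allele(o.get("other_allele"))
            if not (o_eff and o_oth):
                report.append(
                    {"variant_id": vid, "action": "dropped",
                     "reason": "alleles missing on outcome side"}
                )
                continue
            if _is_palindromic(e_eff, e_oth):
                o_eaf = (
                    float(o["eaf"])
                    if "eaf" in out.columns and pd.notna(o.get("eaf"))
                    else None
                )
                resolved = False
                if infer_palindromic and eaf is not None and o_eaf is not None:
                    lo, hi = palindromic_eaf_threshold, 1 - palindromic_eaf_threshold
                    if not (lo < eaf < hi) and not (lo < o_eaf < hi):
                        # decisive frequencies on both sides: same minor
                        # allele side => aligned, opposite => flipped strand
                        sign = 1.0 if (eaf < 0.5) == (o_eaf < 0.5) else -1.0
                        resolved = True
                        report.append(
                            {"variant_id": vid, "action": "kept",
                             "reason": "palindromic resolved by EAF"}
                        )
                if not resolved:
                    report.append(
                        {"variant_id": vid, "action": "dropped",
                         "reason": "palindromic alleles (strand ambiguous)"}
                    )
                    continue
            else:
                kind = _classify_alleles(e_eff, e_oth, o_eff, o_oth)
                if kind == "mismatch":
                    report.append(
                        {"variant_id": vid, "action": "dropped",
                         "reason": f"allele mismatch ({e_eff}/{e_oth} vs {o_eff}/{o_oth})"}
                    )
                    continue
                if kind in ("swap", "flip_swap"):
                    sign = -1.0
                    report.append(
                        {"variant_id": vid, "action": "kept",
                         "reason": f"outcome beta sign-flipped ({kind})"}
                    )
                elif kind == "flip":
                    report.append(
                        {"variant_id": vid, "action": "kept",
                         "reason": "strand flip, orientation preserved"}
                    )
        records.append(
            VariantRecord(
                variant_id=vid,
                beta_exposure=float(e["beta"]),
                se_exposure=float(e["se"]),
                beta_outcome=sign * by,
                se_outcome=float(o["se"]),
                effect_allele=e_eff,
                other_allele=e_oth,
                eaf=eaf,
            )
        )
    if not records:
        raise ValidationError(
            "no variants survived harmonization (all shared variants dropped)"
        )
    meta = {
        "harmonization": "performed" if have_alleles else "skipped",
        "harmonization_report": report,
    }
    return SummarySet(
        tuple(records),
        exposure_label=exposure_label,
        outcome_label=outcome_label,
        meta=meta,
    )


def ratio_estimates(data: SummarySet) -> list[tuple[str, float, float]]:
    """Per-variant ratio (Wald) estimates with first-order standard errors.

    The ratio estimate divides the instrument-outcome association by the
    instrument-exposure association, :math:`\\hat\\beta_j =
    \\hat\\Gamma_j / \\hat\\gamma_j`, with standard error
    :math:`\\sigma_{Yj}/|\\hat\\gamma_j|` — the first-order form that treats
    the exposure association as measured without error.
    """
    zero = [r.variant_id for r in data.records if r.beta_exposure == 0.0]
    if zero:
        raise NullInstrumentError(
            f"ratio estimate undefined for variant(s) with beta_exposure == 0: {zero}"
        )
    return [
        (
            r.variant_id,
            r.beta_outcome / r.beta_exposure,
            r.se_outcome / abs(r.beta_exposure),
        )
        for r in data.records
    ]


def _ratio_arrays(data: SummarySet) -> tuple[np.ndarray, np.ndarray]:
    """(ratios, ratio SEs) as arrays; shared fast path for the estimators."""
    bx = data.beta_exposure
    zero = [v for v, b in zip(data.variant_ids, bx) if b == 0.0]
    if zero:
        raise NullInstrumentError(
            f"ratio estimate undefined for variant(s) with beta_exposure == 0: {zero}"
        )
    return data.beta_outcome / bx, data.se_outcome / np.abs(bx)
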