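"""Reading, writing and preprocessing of salivary biomarker tables.

A cohort is a delimited text table with one row per subject: a unique
``sample_id``, either a precomputed clinical ``group`` column or the three
periodontal parameters it is derived from (``bop_pct``, ``ppd4_pct``,
``cal2_any``), and one column per biomarker concentration (pg/mL scale,
strictly positive).

Group labels follow the convention −1 = gingivitis, +1 = periodontitis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GINGIVITIS = -1
PERIODONTITIS = +1

#: column names that are never treated as biomarkers
_RESERVED = {"sample_id", "group", "bop_pct", "ppd4_pct", "cal2_any"}

_GROUP_ALIASES = {
    "-1": GINGIVITIS, "g": GINGIVITIS, "gin": GINGIVITIS, "gingivitis": GINGIVITIS,
    "1": PERIODONTITIS, "+1": PERIODONTITIS, "p": PERIODONTITIS, "per": PERIODONTITIS,
    "periodontitis": PERIODONTITIS,
}


@dataclass(frozen=True)
class ClinicalRecord:
    """Summary periodontal examination for one subject.

    Parameters
    ----------
    sample_id : str
        Subject identifier.
    bop_pct : float
        Percent of probed sites (six per tooth) with bleeding on probing,
        in [0, 100].
    ppd4_pct : float
        Percent of sites with probing pocket depth >= 4 mm, in [0, 100].
    cal2_any : bool
        Whether any site shows clinical attachment loss >= 2 mm.
    """

    sample_id: str
    bop_pct: float
    ppd4_pct: float
    cal2_any: bool

    def __post_init__(self) -> None:
        for name in ("bop_pct", "ppd4_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v!r} for {self.sample_id!r}: must lie in [0, 100]")


@dataclass
class BiomarkerTable:
    """An m-marker by n-subject concentration matrix with clinical labels.

    ``X`` is stored markers-by-samples (m x n).  Raw tables hold strictly
    positive concentrations; normalized tables hold per-marker z-scores of
    the log concentrations (see :func:`log_normalize`).
    """

    sample_ids: list[str]
    marker_names: list[str]
    X: np.ndarray
    labels: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        m, n = self.X.shape
        if len(self.marker_names) != m or len(self.sample_ids) != n:
            raise ValueError("X shape inconsistent with sample/marker name lists")
        if m < 2:
            raise ValueError("m >= 2 required: pairwise voting needs at least two markers")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.marker_names)) != m:
            raise ValueError("duplicate marker names")
        if np.isnan(self.X).any():
            raise ValueError("missing values in marker matrix")
        if not set(np.unique(self.labels)) <= {GINGIVITIS, PERIODONTITIS}:
            raise ValueError("labels must lie in {-1, +1}")
        for lab in (GINGIVITIS, PERIODONTITIS):
            if (self.labels == lab).sum() < 2:
                raise ValueError(
                    f"label {lab:+d} present fewer than twice; every classifier "
                    "needs at least two training samples per class"
                )
        if not self.normalized and (self.X <= 0).any():
            i, k = np.argwhere(self.X <= 0)[0]
            raise ValueError(
                f"non-positive concentration at sample {self.sample_ids[k]!r}, "
                f"marker {self.marker_names[i]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    @property
    def n_markers(self) -> int:
        return self.X.shape[0]

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, y) in scikit-learn orientation: samples x features."""
        return self.X.T.copy(), self.labels.copy()


def assign_clinical_label(rec: ClinicalRecord) -> int | None:
    """Map a periodontal examination to a disease-group label.

    Gingivitis (−1): bleeding on probing at >= 20% of sites, fewer than 10% of
    sites with pocket depth >= 4 mm, and no site with attachment loss >= 2 mm.
    Periodontitis (+1): bleeding at > 20% of sites, > 10% of sites with pocket
    depth >= 4 mm, and attachment loss >= 2 mm present.

    Returns ``None`` (indeterminate) for presentations matching neither case
    definition — boundary presentations are never silently coerced.
    """
    if rec.bop_pct >= 20 and rec.ppd4_pct < 10 and not rec.cal2_any:
        return GINGIVITIS
    if rec.bop_pct > 20 and rec.ppd4_pct > 10 and rec.cal2_any:
        return PERIODONTITIS
    return None


def _parse_group(value: object, sample_id: str) -> int:
    token = str(value).strip().lower()
    if token not in _GROUP_ALIASES:
        raise ValueError(f"unrecognized group value {value!r} for sample {sample_id!r}")
    return _GROUP_ALIASES[token]


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    token = str(value).strip().lower()
    if token in {"true", "1", "yes"}:
        return True
    if token in {"false", "0", "no"}:
        return False
    raise ValueError(f"unrecognized boolean value {value!r}")


def read_table(path: str | Path, delimiter: str | None = None) -> BiomarkerTable:
    """Read a biomarker cohort from delimited text.

    The delimiter is auto-detected (tab vs comma) unless given.  Leading
    comment lines starting with ``#`` are honoured; a ``# normalized`` line
    marks a table already log-z-normalized by :func:`write_table`.

    Labels come from a ``group`` column when present; otherwise they are
    derived from ``bop_pct``/``ppd4_pct``/``cal2_any`` via
    :func:`assign_clinical_label`, and indeterminate subjects are excluded
    with a logged reason.
    """
    path = Path(path)
    normalized = False
    header_line = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "normalized" in line.lower():
                    normalized = True
                continue
            header_line = line
            break
    if delimiter is None:
        delimiter = "\t" if "\t" in header_line else ","

    df = pd.read_csv(path, sep=delimiter, comment="#")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'sample_id' column")
    if df["sample_id"].isna().any():
        raise ValueError(f"{path}: missing sample IDs")
    sample_ids = [str(s) for s in df["sample_id"]]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample IDs {dupes}")

    if "group" in df.columns:
        labels = np.array([_parse_group(v, s) for v, s in zip(df["group"], sample_ids)])
    elif {"bop_pct", "ppd4_pct", "cal2_any"} <= set(df.columns):
        labels_list, keep = [], []
        for idx, row in df.iterrows():
            rec = ClinicalRecord(
                sample_id=str(row["sample_id"]),
                bop_pct=float(row["bop_pct"]),
                ppd4_pct=float(row["ppd4_pct"]),
                cal2_any=_parse_bool(row["cal2_any"]),
            )
            lab = assign_clinical_label(rec)
            if lab is None:
                logger.info(
                    "excluding sample %s: clinical presentation (BOP %.1f%%, "
                    "PPD>=4mm %.1f%%, CAL>=2mm %s) matches neither case definition",
                    rec.sample_id, rec.bop_pct, rec.ppd4_pct, rec.cal2_any,
                )
                continue
            labels_list.append(lab)
            keep.append(idx)
        df = df.loc[keep]
        sample_ids = [str(s) for s in df["sample_id"]]
        labels = np.array(labels_list)
    else:
        raise ValueError(
            f"{path}: need either a 'group' column or clinical columns "
            "(bop_pct, ppd4_pct, cal2_any) to derive labels"
        )

    marker_names = [c for c in df.columns if c not in _RESERVED]
    if len(marker_names) < 2:
        raise ValueError(f"{path}: m >= 2 required, found {len(marker_names)} marker column(s)")
    try:
        X = df[marker_names].astype(float).to_numpy().T
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric marker value ({exc})") from exc

    return BiomarkerTable(
        sample_ids=sample_ids,
        marker_names=marker_names,
        X=X,
        labels=labels,
        normalized=normalized,
    )


def write_table(table: BiomarkerTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a cohort back to delimited text (round-trips at full precision)."""
    path = Path(path)
    df = pd.DataFrame({"sample_id": table.sample_ids, "group": table.labels})
    for i, name in enumerate(table.marker_names):
        df[name] = table.X[i]
    with open(path, "w") as fh:
        if table.normalized:
            fh.write("# normalized: per-marker z-scores of log concentrations\n")
        df.to_csv(fh, sep=delimiter, index=False)


def log_normalize(table: BiomarkerTable) -> BiomarkerTable:
    """Log-transform and z-normalize each marker to zero mean, unit variance.

    Natural logs; the z-score uses the sample standard deviation (n−1
    denominator) over all n samples.  Normalization is global — computed once
    on the whole cohort before any cross-validation — mirroring preprocessing
    that precedes the voting loop.  The train/test leakage this implies is
    deliberate and documented in the methods note.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    if (table.X <= 0).any():
        i, k = np.argwhere(table.X <= 0)[0]
        raise ValueError(
            f"non-positive value at sample {table.sample_ids[k]!r}, "
            f"marker {table.marker_names[i]!r}; cannot log-transform"
        )
    logged = np.log(table.X)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        i = int(np.argwhere(sd[:, 0] == 0)[0][0])
        raise ValueError(f"marker {table.marker_names[i]!r} is constant; z-score undefined")
    Z = (logged - logged.mean(axis=1, keepdims=True)) / sd
    return replace(table, X=Z, sample_ids=list(table.sample_ids),
                   marker_names=list(table.marker_names), normalized=True)
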