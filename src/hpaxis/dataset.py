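"""Observed-data container for per-individual plasma-GC profiles."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ObservedDataset", "SAMPLING_CLASSES", "normalize_class_label"]

#: Canonical sampling-class labels of a standardized stress series.
SAMPLING_CLASSES = ("baseline", "stress_induced", "post_dex", "post_acth")

REQUIRED_COLUMNS = ("individual_id", "sampling_class", "time_min", "gc_value")
OPTIONAL_COLUMNS = ("gr_expression", "group")

_ALIASES = {
    "b": "baseline",
    "base": "baseline",
    "si": "stress_induced",
    "stress": "stress_induced",
    "stressinduced": "stress_induced",
    "dex": "post_dex",
    "postdex": "post_dex",
    "acth": "post_acth",
    "postacth": "post_acth",
}


def normalize_class_label(label) -> str:
    """Map a free-form class label onto the canonical vocabulary.

    Matching is case-insensitive and ignores spaces/hyphens, e.g.
    ``"Stress-Induced"`` -> ``"stress_induced"``.  Raises ``ValueError``
    for labels outside the four-class vocabulary.
    """
    if not isinstance(label, str):
        raise ValueError(f"sampling_class must be a string, got {label!r}")
    key = label.strip().lower().replace("-", "_").replace(" ", "_")
    if key in SAMPLING_CLASSES:
        return key
    compact = key.replace("_", "")
    if compact in _ALIASES:
        return _ALIASES[compact]
    raise ValueError(
        f"unknown sampling class {label!r}; expected one of {SAMPLING_CLASSES}"
    )


@dataclass
class ObservedDataset:
    """Validated table of GC observations.

    One row per measurement: ``individual_id``, ``sampling_class`` (one of
    ``SAMPLING_CLASSES``), ``time_min`` (minutes since stressor onset) and
    ``gc_value`` (plasma GC, >= 0), optionally with a relative
    ``gr_expression`` covariate and a ``group`` (e.g. species) tag.
    """

    frame: pd.DataFrame

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservedDataset":
        if df is None or len(df) == 0:
            raise ValueError("observations table is empty")
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"observations table is missing columns: {missing}")
        out = df.copy()

        errors: list[str] = []
        labels = []
        for idx, lab in out["sampling_class"].items():
            try:
                labels.append(normalize_class_label(lab))
            except ValueError as exc:
                errors.append(f"row {idx}: {exc}")
                labels.append(None)
        out["sampling_class"] = labels

        time = pd.to_numeric(out["time_min"], errors="coerce")
        gc = pd.to_numeric(out["gc_value"], errors="coerce")
        for idx in out.index[time.isna() | ~np.isfinite(time)]:
            errors.append(f"row {idx}: time_min is not a finite number")
        for idx in out.index[time < 0]:
            errors.append(f"row {idx}: time_min must be >= 0")
        for idx in out.index[gc.isna() | ~np.isfinite(gc)]:
            errors.append(f"row {idx}: gc_value is not a finite number")
        for idx in out.index[gc < 0]:
            errors.append(f"row {idx}: gc_value must be >= 0 (got {out.loc[idx, 'gc_value']})")
        if errors:
            raise ValueError("invalid observations:\n  " + "\n  ".join(errors))
        out["time_min"] = time.astype(float)
        out["gc_value"] = gc.astype(float)
        if "gr_expression" in out.columns:
            out["gr_expression"] = pd.to_numeric(out["gr_expression"], errors="coerce")
        return cls(out.reset_index(drop=True))

    def __post_init__(self):
        # construction through from_frame is canonical; direct construction
        # must already satisfy the contract
        for c in REQUIRED_COLUMNS:
            if c not in self.frame.columns:
                raise ValueError(f"observations table is missing column {c!r}")

    # -- convenience accessors ---------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def individuals(self) -> list:
        return list(pd.unique(self.frame["individual_id"]))

    @property
    def times(self) -> np.ndarray:
        return self.frame["time_min"].to_numpy()

    @property
    def values(self) -> np.ndarray:
        return self.frame["gc_value"].to_numpy()

    def class_means(self) -> pd.Series:
        return self.frame.groupby("sampling_class")["gc_value"].mean()

    def for_individual(self, individual_id) -> "ObservedDataset":
        sub = self.frame[self.frame["individual_id"] == individual_id]
        if len(sub) == 0:
            raise KeyError(f"no observations for individual {individual_id!r}")
        return ObservedDataset(sub.reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
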