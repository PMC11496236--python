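"""Long-format person-wave panel of binary disorder indicators.

The canonical record layout is one row per person-wave with columns
``person_id``, ``wave`` (0-based), eight binary 12-month disorder indicators
(major depression, dysthymia, bipolar disorder, panic disorder, agoraphobia,
social phobia, specific phobia, generalized anxiety disorder), optional
covariate columns, and an optional ``class_truth`` column (1-based latent
class labels, simulation only).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical indicator column names, in fixed order.
INDICATORS = ("mdd", "dys", "bip", "pan", "ago", "soc", "spe", "gad")

#: Human-readable labels for the four default latent classes, prevalence order.
CLASS_LABELS = ("healthy", "depressed-worried", "fear", "high-comorbidity")

_RESERVED = {"person_id", "wave", "baseline", "class_truth"}


class PanelDataset:
    """Person-wave records of binary indicators plus optional covariates.

    Parameters
    ----------
    df
        Long-format table; one row per person-wave. Must contain
        ``person_id``, ``wave`` and at least one indicator column.
    indicators
        Indicator column names, in order. Defaults to the canonical names
        present in ``df`` (in canonical order).
    validate
        Run the structural checks (uniqueness, binary coding, monotone
        dropout) on construction.
    """

    def __init__(self, df: pd.DataFrame, indicators: list[str] | None = None,
                 validate: bool = True):
        if "person_id" not in df.columns or "wave" not in df.columns:
            missing = {"person_id", "wave"} - set(df.columns)
            raise ValidationError(f"missing required column(s): {sorted(missing)}")
        if indicators is None:
            indicators = [c for c in INDICATORS if c in df.columns]
        if not indicators:
            raise ValidationError("no indicator columns found "
                                  f"(expected some of {list(INDICATORS)})")
        for c in indicators:
            if c not in df.columns:
                raise ValidationError(f"missing indicator column: {c!r}")
        self.df = df.reset_index(drop=True)
        self.indicators = list(indicators)
        if validate:
            self._validate()

    # -- structural checks -------------------------------------------------
    def _validate(self) -> None:
        df = self.df
        dup = df.duplicated(subset=["person_id", "wave"])
        if dup.any():
            rows = df.index[dup][:5].tolist()
            raise ValidationError(
                f"duplicate (person_id, wave) pairs at rows {rows}")
        for c in self.indicators:
            col = df[c]
            if col.isna().any():
                rows = df.index[col.isna()][:5].tolist()
                raise ValidationError(
                    f"missing values in indicator {c!r} at rows {rows}")
            bad = ~col.isin([0, 1])
            if bad.any():
                rows = df.index[bad][:5].tolist()
                raise ValidationError(
                    f"non-binary value in indicator {c!r} at rows {rows} "
                    f"(first offending value: {col[bad].iloc[0]!r})")
        # monotone dropout: waves per person must form the prefix 0..t
        waves = df.groupby("person_id")["wave"]
        n_bad = int((waves.max() + 1 != waves.size()).sum())
        if n_bad:
            warnings.warn(
                f"{n_bad} person(s) violate monotone dropout "
                "(waves are not a prefix 0..t); the Markov likelihood "
                "marginalizes the gaps", stacklevel=3)

    # -- accessors ---------------------------------------------------------
    @property
    def y(self) -> np.ndarray:
        """Indicator matrix, shape (n_records, J), dtype int8."""
        return self.df[self.indicators].to_numpy(dtype=np.int8)

    @property
    def wave(self) -> np.ndarray:
        return self.df["wave"].to_numpy(dtype=int)

    @property
    def is_baseline(self) -> np.ndarray:
        """Baseline-measurement flag per record.

        Uses an explicit ``baseline`` column when present (pooled datasets),
        otherwise ``wave == 0``.
        """
        if "baseline" in self.df.columns:
            return self.df["baseline"].to_numpy(dtype=bool)
        return self.wave == 0

    @property
    def person_id(self) -> np.ndarray:
        return self.df["person_id"].to_numpy()

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_persons(self) -> int:
        return self.df["person_id"].nunique()

    @property
    def n_waves(self) -> int:
        return int(self.df["wave"].max()) + 1

    @property
    def J(self) -> int:
        return len(self.indicators)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns
                if c not in _RESERVED and c not in self.indicators]

    @property
    def truth(self) -> np.ndarray | None:
        """0-based true latent class per record, when simulated."""
        if "class_truth" not in self.df.columns:
            return None
        return self.df["class_truth"].to_numpy(dtype=int) - 1

    def subset(self, mask: np.ndarray) -> "PanelDataset":
        return PanelDataset(self.df.loc[mask].reset_index(drop=True),
                            self.indicators, validate=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"PanelDataset(n_records={self.n_records}, "
                f"n_persons={self.n_persons}, J={self.J}, "
                f"covariates={self.covariate_names})")
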