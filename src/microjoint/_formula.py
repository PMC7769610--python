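"""Minimal mixed-model formula language for the longitudinal submodel.

Supported syntax, mirroring the lme4 convention::

    y ~ X1 + Time + X1:Time + (Time|ID)

* the left-hand side (and ``~``) is optional — the response is always the
  focal taxon's counts;
* fixed-effect terms are metadata column names, ``Time`` (the sample
  collection time), or two-way interactions ``A:B``;
* the intercept is implicit in the fixed part, and in every random group;
* exactly one random group ``(1|ID)`` or ``(Time|ID)`` is allowed, giving
  a random intercept or a random intercept + time slope per subject.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Formula"]

_RANDOM_RE = re.compile(r"\(([^|]+)\|([^)]+)\)")


def _term_name(factors: tuple[str, ...]) -> str:
    return ":".join(factors) if factors else "(Intercept)"


@dataclass
class Formula:
    """Parsed fixed/random design specification."""

    fixed_terms: list[tuple[str, ...]] = field(default_factory=list)
    random_terms: list[tuple[str, ...]] = field(default_factory=list)
    group: str = "ID"
    source: str = ""

    @classmethod
    def parse(cls, text: str) -> "Formula":
        src = text
        if "~" in text:
            text = text.split("~", 1)[1]
        random_terms: list[tuple[str, ...]] = [()]
        group = "ID"
        matches = list(_RANDOM_RE.finditer(text))
        if len(matches) > 1:
            raise ValueError("only one random group (terms|group) is supported")
        if matches:
            m = matches[0]
            inner, group = m.group(1).strip(), m.group(2).strip()
            for tok in inner.split("+"):
                tok = tok.strip()
                if tok in ("", "1"):
                    continue
                random_terms.append(tuple(t.strip() for t in tok.split(":")))
            text = _RANDOM_RE.sub("", text)
        fixed_terms: list[tuple[str, ...]] = [()]
        for tok in text.split("+"):
            tok = tok.strip()
            if tok in ("", "1"):
                continue
            fixed_terms.append(tuple(t.strip() for t in tok.split(":")))
        return cls(fixed_terms=fixed_terms, random_terms=random_terms,
                   group=group, source=src)

    @property
    def fixed_names(self) -> list[str]:
        return [_term_name(t) for t in self.fixed_terms]

    @property
    def random_names(self) -> list[str]:
        return [_term_name(t) for t in self.random_terms]

    @property
    def covariate_names(self) -> list[str]:
        """Metadata columns the formula refers to (excluding Time)."""
        out: list[str] = []
        for term in self.fixed_terms + self.random_terms:
            for f in term:
                if f != "Time" and f not in out:
                    out.append(f)
        return out

    def _eval_factor(self, name: str, frame: pd.DataFrame,
                     time: np.ndarray) -> np.ndarray:
        if name == "Time":
            return time
        if name not in frame.columns:
            raise ValueError(f"formula term {name!r} not found in metadata")
        col = frame[name]
        if not pd.api.types.is_numeric_dtype(col):
            raise ValueError(
                f"formula term {name!r} must be numeric (dummy-code factors "
                "before modelling)")
        return col.to_numpy(dtype=float)

    def _build(self, terms, frame: pd.DataFrame, time: np.ndarray) -> np.ndarray:
        cols = []
        for term in terms:
            col = np.ones(len(frame))
            for f in term:
                col = col * self._eval_factor(f, frame, time)
            cols.append(col)
        return np.column_stack(cols)

    def build_design(self, frame: pd.DataFrame,
                     time_col: str = "time") -> tuple[np.ndarray, np.ndarray]:
        """Fixed and random design matrices for observed samples."""
        time = frame[time_col].to_numpy(dtype=float)
        return (self._build(self.fixed_terms, frame, time),
                self._build(self.random_terms, frame, time))

    def design_at_times(self, times, covariates: dict
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Designs for one subject evaluated at arbitrary times.

        ``covariates`` holds that subject's (time-independent) covariate
        values; needed to evaluate the hazard's abundance term at
        quadrature nodes and prediction grids.
        """
        times = np.atleast_1d(np.asarray(times, dtype=float))
        frame = pd.DataFrame({k: np.full(len(times), float(v))
                              for k, v in covariates.items()})
        if not len(frame.columns):
            frame = pd.DataFrame(index=range(len(times)))
        return (self._build(self.fixed_terms, frame, times),
                self._build(self.random_terms, frame, times))
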