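"""Sample matrices of aligned observations.

The central container is :class:`DataMatrix`: ``n`` independent samples
(rows, e.g. individuals of a population) of an ``m``-dimensional random
vector (columns, e.g. codified SNP markers).  Entries may be missing; a
boolean mask marks the observed ones.  Two model families are supported:

* ``"bernoulli"`` — binary entries, e.g. marker ``j`` of individual ``i``
  is 1 iff it lies inside a run of homozygosity for that individual;
* ``"gaussian"`` — real entries, mean and variance both unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

FAMILIES = ("bernoulli", "gaussian")


@dataclass
class DataMatrix:
    """``n × m`` observation matrix with an observed-entry mask.

    Parameters
    ----------
    values : ndarray of shape (n, m)
        Observations, cast to float64.  Unobserved entries may hold any
        value (commonly NaN); they are ignored through ``mask``.
    family : {"bernoulli", "gaussian"}
        Marginal model family of the columns.
    mask : ndarray of bool, shape (n, m), optional
        True where the entry is observed.  Defaults to marking every
        non-NaN entry observed.
    """

    values: np.ndarray
    family: str
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError(
                f"values must be a 2-d matrix, got shape {self.values.shape}"
            )
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValidationError(f"need n >= 1 and m >= 1, got n={n}, m={m}")
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.mask is None:
            self.mask = ~np.isnan(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValidationError(
                    f"mask shape {self.mask.shape} does not match "
                    f"values shape {self.values.shape}"
                )
        if np.isnan(self.values[self.mask]).any():
            raise ValidationError("observed entries (mask=True) must not be NaN")
        if self.family == "bernoulli":
            obs = self.values[self.mask]
            bad = ~np.isin(obs, (0.0, 1.0))
            if bad.any():
                i, j = np.argwhere(self.mask)[np.flatnonzero(bad)[0]]
                raise ValidationError(
                    "bernoulli family requires 0/1 entries; found "
                    f"{self.values[i, j]!r} at row {i + 1}, column {j + 1}"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def select_columns(self, lo: int, hi: int) -> "DataMatrix":
        """Restrict to columns ``lo:hi`` (1-based, inclusive)."""
        if not (1 <= lo <= hi <= self.m):
            raise ValidationError(f"invalid column range {lo}:{hi} for m={self.m}")
        return DataMatrix(
            values=self.values[:, lo - 1 : hi],
            family=self.family,
            mask=self.mask[:, lo - 1 : hi],
        )


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_data_matrix(
    path,
    family: str,
    delimiter: str | None = None,
    header: bool | None = None,
) -> DataMatrix:
    """Read a delimited text matrix (rows = samples, columns = variables).

    Missing values are empty fields or ``NA``.  ``header=None`` autodetects
    a leading row of marker names (any field that does not parse as a
    number or missing-value token).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise ValidationError(f"{path}: empty input file")
    if delimiter is None:
        delimiter = _sniff_delimiter(first)
    if header is None:
        header = False
        for tok in first.rstrip("\n").split(delimiter):
            tok = tok.strip()
            if tok in ("", "NA", "nan", "NaN"):
                continue
            try:
                float(tok)
            except ValueError:
                header = True
                break
    df = pd.read_csv(
        path,
        sep=delimiter,
        header=0 if header else None,
        na_values=["NA", ""],
    )
    values = df.to_numpy(dtype=np.float64)
    return DataMatrix(values=values, family=family)


def write_data_matrix(data: DataMatrix, path, delimiter: str = "\t") -> None:
    """Write a matrix as delimited text; unobserved entries become ``NA``."""
    out = data.values.astype(object)
    out[~data.mask] = "NA"
    if data.family == "bernoulli":
        obs = data.mask
        tmp = np.empty_like(out)
        tmp[obs] = data.values[obs].astype(np.int64)
        tmp[~obs] = "NA"
        out = tmp
    pd.DataFrame(out).to_csv(path, sep=delimiter, header=False, index=False)
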