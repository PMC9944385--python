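"""National life tables: the mortality input for the illness–death model.

A life table tabulates ``qx``, the probability that a person of a given
sex who has reached age ``x`` (in completed years) dies before reaching
age ``x + 1``.  The Markov engine converts ``qx`` to an annual hazard
``h = -ln(1 - qx)``, assumed constant within the year of age — the
standard actuarial approximation.

Tables are read from CSV with columns ``sex,age,qx``.  A synthetic
Gompertz-shaped fixture (``fixtures/lifetable_synthetic.csv``) ships with
the package so that nothing needs to be downloaded; users may substitute
a real national table (for instance an ONS period life table) with the
same schema.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

#: Gompertz parameters of the packaged synthetic fixture, chosen so that
#: life expectancy at birth is ~79 years for men and ~83 for women.
GOMPERTZ_B = 0.09
GOMPERTZ_A = {"male": 4.231e-05, "female": 2.922e-05}


class LifeTableError(ValueError):
    """Raised for malformed or incomplete life tables."""


@dataclass(frozen=True)
class LifeTable:
    """Sex-by-age annual death probabilities.

    Parameters
    ----------
    data
        DataFrame with columns ``sex`` ("male"/"female"), ``age``
        (integer, contiguous per sex) and ``qx`` in [0, 1].
    """

    data: pd.DataFrame
    _qx: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        df = self.data
        missing = {"sex", "age", "qx"} - set(df.columns)
        if missing:
            raise LifeTableError(f"life table missing columns: {sorted(missing)}")
        qx = {}
        for sex in SEXES:
            sub = df[df["sex"] == sex].sort_values("age")
            if sub.empty:
                raise LifeTableError(f"life table has no rows for sex={sex!r}")
            ages = sub["age"].to_numpy()
            bad = sub[(sub["qx"] < 0) | (sub["qx"] > 1) | sub["qx"].isna()]
            if not bad.empty:
                row = bad.iloc[0]
                raise LifeTableError(
                    f"qx={row['qx']} outside [0, 1] at sex={sex!r} age={int(row['age'])}"
                )
            gaps = np.flatnonzero(np.diff(ages) != 1)
            if gaps.size:
                raise LifeTableError(
                    f"age gap for sex={sex!r} between {int(ages[gaps[0]])} "
                    f"and {int(ages[gaps[0] + 1])}"
                )
            qx[sex] = (int(ages[0]), sub["qx"].to_numpy(float))
        if self.min_age(df) > 18 or self.max_age(df) < 100:
            raise LifeTableError(
                "life table must cover at least ages 18 through 100 "
                f"(got {self.min_age(df)}..{self.max_age(df)})"
            )
        object.__setattr__(self, "_qx", qx)

    @staticmethod
    def min_age(df) -> int:
        return int(df["age"].min())

    @staticmethod
    def max_age(df) -> int:
        return int(df["age"].max())

    @property
    def age_min(self) -> int:
        return self.min_age(self.data)

    @property
    def age_max(self) -> int:
        return self.max_age(self.data)

    def qx(self, sex: str, age: int) -> float:
        """Annual death probability for one (sex, age) cell.

        Ages above the tabulated maximum are clamped to the terminal row
        (with a warning); ages below the minimum are an error.
        """
        return float(self.qx_vector(sex, np.asarray([age]))[0])

    def qx_vector(self, sex: str, ages: np.ndarray) -> np.ndarray:
        if sex not in SEXES:
            raise LifeTableError(f"unknown sex {sex!r}; expected one of {SEXES}")
        a0, q = self._qx[sex]
        ages = np.asarray(ages, dtype=int)
        if (ages < a0).any():
            raise LifeTableError(
                f"age {int(ages.min())} below life-table minimum {a0} for sex={sex!r}"
            )
        amax = a0 + len(q) - 1
        if (ages > amax).any():
            logger.warning(
                "age above life-table maximum %d clamped to terminal qx", amax
            )
        return q[np.minimum(ages, amax) - a0]

    def annual_hazard(self, sex: str, age: int) -> float:
        """-ln(1 - qx), the constant-within-year mortality hazard."""
        q = self.qx(sex, age)
        return -np.log(max(1.0 - q, 1e-300))

    def survival(self, sex: str, age_from: int, age_to: int) -> float:
        """Probability of surviving from ``age_from`` to ``age_to``: prod(1-qx)."""
        if age_to < age_from:
            raise LifeTableError("age_to must be >= age_from")
        ages = np.arange(age_from, age_to)
        if ages.size == 0:
            return 1.0
        return float(np.prod(1.0 - self.qx_vector(sex, ages)))


def death_probability(table: LifeTable, sex: str, age: int) -> float:
    """Annual probability of death before next birthday for (sex, age)."""
    return table.qx(sex, age)


def load_life_table(path) -> LifeTable:
    """Read and validate a ``sex,age,qx`` CSV life table."""
    df = pd.read_csv(path)
    return LifeTable(df)


def synthetic_life_table(
    max_age: int = 100,
    a: dict | None = None,
    b: float = GOMPERTZ_B,
    terminal_qx: float = 1.0,
) -> LifeTable:
    """Gompertz life table qx = min(1, A·exp(B·age)) with a terminal row.

    The terminal age receives ``terminal_qx`` (default 1) so that cohort
    computations close out at ``max_age``.
    """
    a = dict(GOMPERTZ_A if a is None else a)
    ages = np.arange(0, max_age + 1)
    frames = []
    for sex in SEXES:
        qx = np.minimum(1.0, a[sex] * np.exp(b * ages))
        qx[-1] = terminal_qx
        frames.append(pd.DataFrame({"sex": sex, "age": ages, "qx": qx}))
    return LifeTable(pd.concat(frames, ignore_index=True))


def constant_life_table(qx: float, max_age: int = 100) -> LifeTable:
    """Life table with the same qx at every age — used for closed-form checks."""
    ages = np.arange(0, max_age + 1)
    frames = [pd.DataFrame({"sex": s, "age": ages, "qx": qx}) for s in SEXES]
    return LifeTable(pd.concat(frames, ignore_index=True))


def packaged_life_table() -> LifeTable:
    """The synthetic fixture shipped inside the package."""
    with resources.as_file(
        resources.files("ddepi").joinpath("fixtures/lifetable_synthetic.csv")
    ) as p:
        return load_life_table(p)


def write_life_table(table: LifeTable, path) -> None:
    table.data.to_csv(path, index=False)
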