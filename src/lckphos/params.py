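"""Kinetic parameters of the LCK/CSK trans-phosphorylation model.

The model describes membrane-anchored LCK molecules that phosphorylate each
other in *trans* at two regulatory tyrosines, the activating Y394 and the
inhibitory Y505, plus the kinase CSK which phosphorylates LCK only at Y505.
Each enzyme--substrate dimer follows a Michaelis--Menten scheme

    E + S  <-> E.S  -> E + P        (k_on shared, k_off and k_cat per pair)

with a single association rate ``k_on`` shared by all 16 LCK--LCK pairs, a
second shared association rate ``k_on_csk`` for the two CSK--LCK pairs, and a
per-pair dissociation and catalytic rate.  That gives 38 kinetic parameters:

    1 (k_on) + 1 (k_on_csk) + 16 (k_off) + 16 (k_cat) + 2 (k_off CSK)
    + 2 (k_cat CSK)

Units: densities in molecules/um^2, time in seconds, ``k_on`` in
um^2/(molecule*s), all other rates in 1/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

#: The four LCK phospho-forms in canonical order: (Y394, Y505) status.
FORMS: tuple[str, ...] = ("UU", "PU", "UP", "PP")

#: Valid substrate sites: a site must be unphosphorylated on its host form.
#: (site, host_form); Y394 exists on UU and UP, Y505 on UU and PU.
SUBSTRATE_SITES: tuple[tuple[str, str], ...] = (
    ("Y394", "UU"),
    ("Y505", "UU"),
    ("Y505", "PU"),
    ("Y394", "UP"),
)

#: LCK enzyme-substrate pairs in the canonical (published table) row order.
#: Entry i (1-based index i+1) is (enzyme_form, site, host_form) and owns
#: rates k_off_{i+1} and k_cat_{i+1}.
LCK_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("UU", "Y394", "UU"),
    ("UU", "Y505", "UU"),
    ("UU", "Y505", "PU"),
    ("PU", "Y394", "UU"),
    ("PU", "Y505", "UU"),
    ("UU", "Y394", "UP"),
    ("UP", "Y394", "UU"),
    ("UP", "Y505", "UU"),
    ("PU", "Y505", "PU"),
    ("UP", "Y505", "PU"),
    ("PU", "Y394", "UP"),
    ("UP", "Y394", "UP"),
    ("PP", "Y394", "UU"),
    ("PP", "Y505", "UU"),
    ("PP", "Y505", "PU"),
    ("PP", "Y394", "UP"),
)

#: CSK pairs: CSK phosphorylates Y505 on UU and on PU only.
CSK_PAIRS: tuple[tuple[str, str], ...] = (("Y505", "UU"), ("Y505", "PU"))

#: (enzyme_form, site, host_form) -> 1-based pair index.
PAIR_INDEX: dict[tuple[str, str, str], int] = {
    p: i + 1 for i, p in enumerate(LCK_PAIRS)
}

#: Flat parameter names in vector order.
PARAM_NAMES: tuple[str, ...] = (
    ("k_on", "k_on_csk")
    + tuple(f"k_off_{i}" for i in range(1, 17))
    + tuple(f"k_cat_{i}" for i in range(1, 17))
    + ("k_off_csk_uu", "k_off_csk_pu", "k_cat_csk_uu", "k_cat_csk_pu")
)

N_PARAMS = len(PARAM_NAMES)  # 38


def phosphorylate(form: str, site: str) -> str:
    """Return the phospho-form obtained by phosphorylating ``site`` on ``form``.

    Raises ``ValueError`` if the site is already phosphorylated on that form.
    """
    y394, y505 = form[0], form[1]
    if site == "Y394":
        if y394 != "U":
            raise ValueError(f"Y394 already phosphorylated on {form}")
        return "P" + y505
    if site == "Y505":
        if y505 != "U":
            raise ValueError(f"Y505 already phosphorylated on {form}")
        return y394 + "P"
    raise ValueError(f"unknown site {site!r}")


@dataclass
class RateParameterSet:
    """The 38 kinetic rate constants of the model (theta).

    ``k_off``/``k_cat`` are length-16 arrays in canonical pair order;
    ``k_off_csk``/``k_cat_csk`` are length-2 arrays ordered (UU, PU).
    """

    k_on: float
    k_on_csk: float
    k_off: np.ndarray
    k_cat: np.ndarray
    k_off_csk: np.ndarray
    k_cat_csk: np.ndarray

    def __post_init__(self) -> None:
        self.k_off = np.asarray(self.k_off, dtype=float)
        self.k_cat = np.asarray(self.k_cat, dtype=float)
        self.k_off_csk = np.asarray(self.k_off_csk, dtype=float)
        self.k_cat_csk = np.asarray(self.k_cat_csk, dtype=float)
        if self.k_off.shape != (16,) or self.k_cat.shape != (16,):
            raise ValueError("k_off and k_cat must have 16 entries")
        if self.k_off_csk.shape != (2,) or self.k_cat_csk.shape != (2,):
            raise ValueError("CSK rate arrays must have 2 entries")
        vec = self.to_vector()
        if not np.all(np.isfinite(vec)) or np.any(vec < 0):
            raise ValueError("all rates must be finite and >= 0")

    # -- vector / dict round trips -------------------------------------------------

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical 38-vector (see ``PARAM_NAMES``)."""
        return np.concatenate(
            [
                [self.k_on, self.k_on_csk],
                self.k_off,
                self.k_cat,
                self.k_off_csk,
                self.k_cat_csk,
            ]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "RateParameterSet":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (N_PARAMS,):
            raise ValueError(f"expected a {N_PARAMS}-vector, got shape {vec.shape}")
        return cls(
            k_on=float(vec[0]),
            k_on_csk=float(vec[1]),
            k_off=vec[2:18].copy(),
            k_cat=vec[18:34].copy(),
            k_off_csk=vec[34:36].copy(),
            k_cat_csk=vec[36:38].copy(),
        )

    def to_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, map(float, self.to_vector())))

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "RateParameterSet":
        missing = [n for n in PARAM_NAMES if n not in d]
        if missing:
            raise KeyError(f"missing parameters: {missing}")
        return cls.from_vector(np.array([d[n] for n in PARAM_NAMES]))

    def value_of(self, name: str) -> float:
        """Look up a single rate by its flat name (e.g. ``k_off_5``)."""
        idx = PARAM_NAMES.index(name)
        return float(self.to_vector()[idx])

    def replace(self, **updates: float) -> "RateParameterSet":
        """Return a copy with named rates replaced."""
        d = self.to_dict()
        for name, value in updates.items():
            if name not in d:
                raise KeyError(name)
            d[name] = float(value)
        return RateParameterSet.from_dict(d)

    # -- derived quantities ---------------------------------------------------------

    def k_d(self) -> np.ndarray:
        """Per-pair dissociation constants k_off/k_on (molecules/um^2)."""
        if self.k_on <= 0:
            raise ZeroDivisionError("k_d undefined for k_on == 0")
        return self.k_off / self.k_on

    # -- I/O --------------------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RateParameterSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _data_text(name: str) -> str:
    return resources.files("lckphos.data").joinpath(name).read_text()


def table1_median() -> RateParameterSet:
    """Median rates of the published best-fit ensemble (the canonical baseline)."""
    return RateParameterSet.from_dict(json.loads(_data_text("table1_median.json")))


def table1_ci() -> dict[str, tuple[float, float]]:
    """Per-parameter 90% confidence intervals, transcribed verbatim."""
    raw = json.loads(_data_text("table1_ci.json"))
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}


def ci_inconsistencies() -> list[str]:
    """Names of parameters whose published median falls outside its printed CI.

    Several printed intervals do not bracket their medians; they are
    transcribed as-is rather than silently corrected, and this helper makes
    the anomaly explicit for downstream users.
    """
    med = table1_median().to_dict()
    ci = table1_ci()
    return [n for n in PARAM_NAMES if not (ci[n][0] <= med[n] <= ci[n][1])]
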