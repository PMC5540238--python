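"""Vesicle aggregation-number and enzyme-loading arithmetic.

A polymersome membrane is a spherical shell of hydrophobic copolymer
blocks sandwiched between hydrophilic brushes.  The number of copolymer
chains per vesicle (the aggregation number) follows from shell volume
over single-chain volume:

    N_agg(R) = (4/3) π [(R − l_b)³ − (R − l_b − t_m)³] / ν_chain

with R the vesicle radius, l_b the hydrophilic brush length, t_m the
membrane thickness and ν_chain the molecular volume of one hydrophobic
chain.  Given the copolymer amount [P] (mol) and a measured size
distribution {(R_i, Φ_i)}, the vesicle count partitions the total chain
count by the per-size aggregation number:

    N_ps = Σ_i [P] · N_A · Φ_i / N_agg(R_i)

and the encapsulation efficiency is enzymes per vesicle, e = N_e / N_ps.

Note on the vesicle-count formula: the source material typesets it as a
product with N_agg and Φ_i R_i; read literally that expression is not
dimensionally a vesicle count.  The division by N_agg(R_i) used here is
the dimensionally coherent reading (total chains partitioned into
vesicles of each size) and is flagged as an interpretation, not as the
original authors' typesetting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, GeometryError, ParameterError
from .physics import AVOGADRO_PER_MOL


def aggregation_number(R_nm: float, l_b_nm: float, t_m_nm: float,
                       v_chain_nm3: float) -> float:
    """Copolymer chains per vesicle from shell-volume arithmetic."""
    if not (v_chain_nm3 > 0):
        raise ParameterError("chain molecular volume must be positive")
    if l_b_nm < 0 or t_m_nm < 0:
        raise GeometryError("brush length and membrane thickness must be non-negative")
    outer = R_nm - l_b_nm
    inner = outer - t_m_nm
    if not (inner >= 0 and outer > 0):
        raise GeometryError(
            f"shell is degenerate: R={R_nm}, l_b={l_b_nm}, t_m={t_m_nm} nm")
    shell = (4.0 / 3.0) * math.pi * (outer**3 - inner**3)
    return shell / v_chain_nm3


@dataclass(frozen=True)
class LoadingInputs:
    """Size distribution and molecular parameters of one preparation.

    ``size_distribution`` maps vesicle radius (nm) to number fraction;
    fractions must sum to 1.  ``copolymer_mol`` is the copolymer amount
    [P] in mol; ``n_enzymes`` the total enzyme count in the sample.
    """

    size_distribution: tuple  # ((R_nm, fraction), ...)
    l_b_nm: float
    t_m_nm: float
    v_chain_nm3: float
    copolymer_mol: float
    n_enzymes: float = 0.0

    def __post_init__(self) -> None:
        dist = tuple(self.size_distribution)
        if not dist:
            raise DataError("size distribution is empty")
        total = sum(f for _, f in dist)
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"size fractions must sum to 1, got {total}")
        if any(f < 0 for _, f in dist):
            raise DataError("size fractions must be non-negative")
        if self.copolymer_mol <= 0:
            raise ParameterError("copolymer amount must be positive")
        if self.n_enzymes < 0:
            raise ParameterError("enzyme count must be non-negative")
        for R, _ in dist:
            if R <= self.l_b_nm + self.t_m_nm:
                raise GeometryError(
                    f"radius {R} nm does not accommodate brush + membrane")
        object.__setattr__(self, "size_distribution", dist)


def polymersome_count(inputs: LoadingInputs) -> float:
    """Number of vesicles: total chains partitioned by per-size N_agg."""
    chains_total = inputs.copolymer_mol * AVOGADRO_PER_MOL
    return sum(
        chains_total * frac / aggregation_number(
            R, inputs.l_b_nm, inputs.t_m_nm, inputs.v_chain_nm3)
        for R, frac in inputs.size_distribution
    )


def encapsulation_efficiency(n_enzymes: float, n_polymersomes: float) -> float:
    """Enzymes per vesicle, e = N_e / N_ps."""
    if n_polymersomes <= 0:
        raise ParameterError("vesicle count must be positive")
    if n_enzymes < 0:
        raise ParameterError("enzyme count must be non-negative")
    return n_enzymes / n_polymersomes


def loading_report(inputs: LoadingInputs) -> pd.DataFrame:
    """Per-size-bin table: radius, fraction, N_agg, vesicle count share."""
    chains_total = inputs.copolymer_mol * AVOGADRO_PER_MOL
    rows = []
    for R, frac in inputs.size_distribution:
        n_agg = aggregation_number(R, inputs.l_b_nm, inputs.t_m_nm,
                                   inputs.v_chain_nm3)
        rows.append({
            "radius_nm": R,
            "fraction": frac,
            "n_agg": n_agg,
            "n_vesicles": chains_total * frac / n_agg,
        })
    return pd.DataFrame(rows)


def read_size_distribution(path) -> tuple:
    """Two-column delimited text (R_nm, fraction) -> size distribution."""
    df = pd.read_csv(path, comment="#", header=None,
                     names=["R_nm", "fraction"], sep=None, engine="python")
    try:
        vals = [(float(r), float(f)) for r, f in df.itertuples(index=False)]
    except (TypeError, ValueError) as exc:
        raise DataError(f"malformed size distribution file: {exc}") from exc
    return tuple(vals)
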