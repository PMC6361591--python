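"""Fatty-chain nomenclature, alcohol/acyl pairing and the fatty-alcohol ratio.

Fatty-chain descriptors follow the compact field notation: carbon-chain
length, double bonds either with position/configuration (``Z9,Z12-18``) or as
a bare count when isomers were not resolved (``22:1``), and a C1 moiety token
(``OH`` alcohol, ``COOH`` free acid, ``Me`` methyl ester, ``CoA`` thioester;
a trailing bare colon denotes the pooled transesterifiable acyl).

The fatty-alcohol ratio of a chain structure X is

    ratio(X) = 100 * n(alcohol X) / (n(alcohol X) + n(acyl X))   [percent]

with amounts in moles and the acyl term pooling all transesterifiable acyls
(free acids, esters, CoA thioesters) with the same chain structure.  It is
the apparent degree of conversion of the acyl pool to the alcohol and is used
as an in-vivo / expression-system readout of FAR enzyme specificity.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ALCOHOL_MOIETY = "OH"
ACYL_MOIETIES = ("COOH", "Me", "CoA", "acyl_total")
MOIETIES = (ALCOHOL_MOIETY,) + ACYL_MOIETIES

_ATOMIC = {"C": 12.011, "H": 1.008, "O": 15.999}


class ChainParseError(ValueError):
    """Raised when a chain descriptor string cannot be parsed."""


@dataclass(frozen=True)
class ChainDescriptor:
    """A fatty chain: length, unsaturation and (optionally) bond positions."""

    carbons: int
    n_double_bonds: int
    double_bonds: tuple[tuple[int, str], ...] = ()
    positions_known: bool = True

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("chain needs at least 2 carbons")
        if self.n_double_bonds < 0:
            raise ValueError("negative double bond count")
        if self.positions_known:
            if len(self.double_bonds) != self.n_double_bonds:
                raise ValueError("positions_known but bond list length != count")
            positions = [p for p, _ in self.double_bonds]
            if positions != sorted(set(positions)):
                raise ValueError("double-bond positions must be strictly increasing")
            if positions and positions[-1] >= self.carbons:
                raise ValueError("double-bond position beyond chain length")
            for _, config in self.double_bonds:
                if config not in ("Z", "E"):
                    raise ValueError(f"double-bond configuration must be Z/E, got {config!r}")
        elif self.double_bonds:
            raise ValueError("positions_known=False excludes an explicit bond list")

    @property
    def key_exact(self) -> tuple:
        return (self.carbons, self.n_double_bonds, self.double_bonds)

    @property
    def key_loose(self) -> tuple:
        """Chain identity up to unresolved double-bond positions."""
        return (self.carbons, self.n_double_bonds)

    def format(self, moiety: str = "") -> str:
        """Canonical descriptor string, e.g. ``Z9,Z12-18:OH`` or ``22:1``."""
        if self.positions_known and self.double_bonds:
            prefix = ",".join(f"{cfg}{pos}" for pos, cfg in self.double_bonds) + "-"
            body = f"{prefix}{self.carbons}:"
        elif not self.positions_known:
            body = f"{self.carbons}:{self.n_double_bonds}"
            return f"{body}:{moiety}" if moiety else body
        else:
            body = f"{self.carbons}:"
        return f"{body}{moiety}" if moiety else body


_DESCRIPTOR_RE = re.compile(
    r"^(?:(?P<bonds>[ZE]\d+(?:,[ZE]\d+)*)-)?(?P<carbons>\d+):(?P<rest>.*)$"
)


def parse_chain(descriptor: str, default_moiety: str | None = None) -> tuple[ChainDescriptor, str]:
    """Parse a descriptor string into ``(ChainDescriptor, moiety)``.

    ``"Z9,Z12-18:OH"`` -> 18 carbons, bonds (9, Z), (12, Z), moiety ``OH``;
    ``"22:1"`` -> 22 carbons, one double bond with unresolved position (the
    moiety then comes from *default_moiety*, or a third ``:``-field);
    ``"Z9-16:"`` -> the pooled acyl of the Z9-hexadecenoyl chain.
    """
    text = descriptor.strip()
    match = _DESCRIPTOR_RE.match(text)
    if not match:
        raise ChainParseError(f"cannot parse chain descriptor {descriptor!r}")
    carbons = int(match.group("carbons"))
    bonds_text = match.group("bonds")
    rest = match.group("rest").strip()

    count_text: str | None = None
    moiety_text: str | None = None
    if rest:
        parts = rest.split(":")
        if len(parts) == 1:
            if parts[0].isdigit():
                count_text = parts[0]
            else:
                moiety_text = parts[0]
        elif len(parts) == 2 and parts[0].isdigit():
            count_text, moiety_text = parts[0], parts[1] or None
        else:
            raise ChainParseError(f"unrecognised token {rest!r} in {descriptor!r}")

    if moiety_text is None:
        moiety = default_moiety if default_moiety is not None else "acyl_total"
    else:
        moiety = moiety_text
    if moiety not in MOIETIES:
        raise ChainParseError(f"unknown moiety token {moiety!r} in {descriptor!r}")

    if bonds_text and count_text:
        raise ChainParseError(
            f"descriptor {descriptor!r} gives both bond positions and a bond count"
        )
    if bonds_text:
        bonds = tuple(
            (int(token[1:]), token[0]) for token in bonds_text.split(",")
        )
        try:
            chain = ChainDescriptor(carbons, len(bonds), bonds, positions_known=True)
        except ValueError as exc:
            raise ChainParseError(f"{descriptor!r}: {exc}") from None
    elif count_text:
        n = int(count_text)
        chain = ChainDescriptor(carbons, n, (), positions_known=(n == 0))
    else:
        chain = ChainDescriptor(carbons, 0, (), positions_known=True)
    return chain, moiety


@dataclass(frozen=True)
class LipidMeasurement:
    """Molar amount of one alcohol or acyl species in one sample."""

    chain: ChainDescriptor
    moiety: str
    amount_nmol: float
    sample_id: str = ""
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.moiety not in MOIETIES:
            raise ValueError(f"unknown moiety {self.moiety!r}")
        if self.amount_nmol < 0:
            raise ValueError("amount must be >= 0")


def molecular_weight(chain: ChainDescriptor, moiety: str) -> float:
    """Molecular weight (g/mol) implied by the descriptor.

    Alcohol: CnH(2n+2-2d)O; methyl ester: C(n+1)H(2n+2-2d)O2; free acid:
    CnH(2n-2d)O2 (n = chain carbons, d = double bonds).
    """
    n, d = chain.carbons, chain.n_double_bonds
    if moiety == ALCOHOL_MOIETY:
        c, h, o = n, 2 * n + 2 - 2 * d, 1
    elif moiety == "Me":
        c, h, o = n + 1, 2 * n + 2 - 2 * d, 2
    elif moiety == "COOH":
        c, h, o = n, 2 * n - 2 * d, 2
    else:
        raise ValueError(f"no molecular formula defined for moiety {moiety!r}")
    return c * _ATOMIC["C"] + h * _ATOMIC["H"] + o * _ATOMIC["O"]


def ug_to_nmol(amount_ug: float, chain: ChainDescriptor, moiety: str) -> float:
    """Convert a mass (ug) to nmol via the formula weight of the species."""
    return amount_ug * 1000.0 / molecular_weight(chain, moiety)


@dataclass(frozen=True)
class RatioResult:
    """Fatty-alcohol ratio of one chain in one sample."""

    chain: ChainDescriptor
    sample_id: str
    alcohol_nmol: float
    acyl_nmol: float
    ratio_percent: float | None


def fatty_alcohol_ratio(alcohol_nmol: float, acyl_nmol: float) -> float | None:
    """``100 * a / (a + b)``; undefined (None) when both amounts are zero."""
    if alcohol_nmol < 0 or acyl_nmol < 0:
        raise ValueError("amounts must be >= 0")
    total = alcohol_nmol + acyl_nmol
    if total == 0:
        return None
    return 100.0 * alcohol_nmol / total


def pair_measurements(
    measurements: Iterable[LipidMeasurement], sample_id: str
) -> list[tuple[ChainDescriptor, float, float]]:
    """Match alcohols of one sample to their pooled same-chain acyl amounts.

    All acyl moieties (free acid, methyl-ester-detected, CoA, pooled) are
    summed.  Chains match exactly on double-bond positions when both sides
    resolved them; when either side reports only a bond count, matching falls
    back to (carbons, n_double_bonds) and sums over isomers.  Unmatched
    alcohols pair with acyl amount 0 and vice versa.

    Returns ``(chain, alcohol_nmol, acyl_nmol)`` triples sorted by chain.
    """
    sample = [m for m in measurements if m.sample_id == sample_id]
    alcohols: dict[ChainDescriptor, float] = {}
    acyls: dict[ChainDescriptor, float] = {}
    for m in sample:
        bucket = alcohols if m.moiety == ALCOHOL_MOIETY else acyls
        bucket[m.chain] = bucket.get(m.chain, 0.0) + m.amount_nmol

    def acyl_amount_for(chain: ChainDescriptor) -> tuple[float, set[ChainDescriptor]]:
        matched: set[ChainDescriptor] = set()
        total = 0.0
        for acyl_chain, amount in acyls.items():
            if acyl_chain.key_loose != chain.key_loose:
                continue
            if chain.positions_known and acyl_chain.positions_known:
                if acyl_chain.double_bonds != chain.double_bonds:
                    continue
            total += amount
            matched.add(acyl_chain)
        return total, matched

    pairs: list[tuple[ChainDescriptor, float, float]] = []
    consumed: set[ChainDescriptor] = set()
    for chain in sorted(alcohols, key=lambda c: (c.carbons, c.n_double_bonds, c.double_bonds)):
        acyl_total, matched = acyl_amount_for(chain)
        consumed |= matched
        pairs.append((chain, alcohols[chain], acyl_total))
    for chain in sorted(
        set(acyls) - consumed, key=lambda c: (c.carbons, c.n_double_bonds, c.double_bonds)
    ):
        pairs.append((chain, 0.0, acyls[chain]))
    return pairs


def specificity_profile(
    measurements: Iterable[LipidMeasurement], sample_ids: Sequence[str]
) -> pd.DataFrame:
    """Per-chain fatty-alcohol ratios across replicate samples.

    One row per chain with the per-replicate ratios, their mean and sd
    (chains undefined in a replicate are missing for that replicate, not
    zero), plus the ratio of mean amounts as an alternative pooled summary.
    """
    if not sample_ids:
        raise ValueError("need at least one sample id")
    measurements = list(measurements)
    per_sample: dict[str, dict[tuple, tuple[ChainDescriptor, float, float]]] = {}
    chains: dict[tuple, ChainDescriptor] = {}
    for sid in sample_ids:
        pairs = pair_measurements(measurements, sid)
        per_sample[sid] = {}
        for chain, a, b in pairs:
            key = (chain.carbons, chain.n_double_bonds, chain.double_bonds, chain.positions_known)
            chains[key] = chain
            per_sample[sid][key] = (chain, a, b)

    rows = []
    for key in sorted(chains):
        chain = chains[key]
        ratios, amounts_a, amounts_b = [], [], []
        for sid in sample_ids:
            entry = per_sample[sid].get(key)
            if entry is None:
                continue
            _, a, b = entry
            r = fatty_alcohol_ratio(a, b)
            if r is not None:
                ratios.append(r)
                amounts_a.append(a)
                amounts_b.append(b)
        mean_ratio = float(np.mean(ratios)) if ratios else math.nan
        sd_ratio = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else math.nan
        pooled = (
            fatty_alcohol_ratio(float(np.mean(amounts_a)), float(np.mean(amounts_b)))
            if amounts_a
            else None
        )
        rows.append(
            {
                "chain": chain.format(),
                "n_replicates": len(ratios),
                "mean_ratio_percent": mean_ratio,
                "sd_ratio_percent": sd_ratio,
                "ratio_of_mean_amounts_percent": pooled if pooled is not None else math.nan,
            }
        )
    return pd.DataFrame(rows)


def read_lipid_csv(path: str | Path, mass_mode: bool = False) -> list[LipidMeasurement]:
    """Read a lipid table CSV into measurements.

    Columns: ``sample_id, tissue, descriptor, amount_nmol`` (or ``amount_ug``
    with ``mass_mode=True``, converted via the formula weight).
    """
    table = pd.read_csv(path)
    amount_col = "amount_ug" if mass_mode else "amount_nmol"
    required = {"sample_id", "tissue", "descriptor", amount_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"lipid CSV missing columns: {sorted(missing)}")
    out = []
    for row in table.itertuples(index=False):
        chain, moiety = parse_chain(getattr(row, "descriptor"))
        amount = float(getattr(row, amount_col))
        if mass_mode:
            amount = ug_to_nmol(amount, chain, moiety)
        out.append(
            LipidMeasurement(
                chain=chain,
                moiety=moiety,
                amount_nmol=amount,
                sample_id=str(getattr(row, "sample_id")),
                tissue=str(getattr(row, "tissue")),
            )
        )
    return out
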