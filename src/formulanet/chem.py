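"""Quantitative estimate of drug-likeness (QED) screening.

QED (Bickerton et al. 2012) summarises eight physicochemical descriptors —
molecular mass (MW), octanol-water partition coefficient (ALOGP),
hydrogen-bond acceptors (HBA) and donors (HBD), polar surface area (PSA),
rotatable bonds (ROTB), aromatic rings (AROM) and structural alerts
(ALERTS) — by mapping each through an asymmetric double-sigmoid
desirability function d_i in (0, 1] and taking the weighted geometric mean

    QED = exp( sum_i w_i ln d_i(x_i) / sum_i w_i ).

The desirability coefficients and the mean-weighting scheme are pinned in
a bundled parameter file so that alternative parameterisations can be
swapped in as data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from .io import DESCRIPTOR_COLUMNS

#: desirabilities are floored here before taking logarithms, so a single
#: pathological descriptor cannot produce -inf; affects only compounds far
#: outside drug-like space, which fail the filter regardless
DESIRABILITY_FLOOR = 1e-6


@dataclass
class CompoundRecord:
    """One compound with its eight drug-likeness descriptors."""

    compound_id: str
    mw: float
    alogp: float
    hba: int
    hbd: int
    psa: float
    rotb: int
    arom: int
    alerts: int
    herb_ids: frozenset[str] = field(default_factory=frozenset)
    qed: float | None = None

    def descriptor(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass(frozen=True)
class ADSCoefficients:
    """Asymmetric double-sigmoid desirability d(x) for one property."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    dmax: float

    def __call__(self, x: float) -> float:
        num = self.a + self.b / (1.0 + math.exp(-(x - self.c + self.d / 2.0) / self.e)) * (
            1.0 - 1.0 / (1.0 + math.exp(-(x - self.c - self.d / 2.0) / self.f))
        )
        return num / self.dmax


@dataclass(frozen=True)
class QEDParams:
    """Per-property desirability coefficients plus non-negative weights."""

    desirabilities: dict[str, ADSCoefficients]
    weights: dict[str, float]

    def __post_init__(self):
        if set(self.desirabilities) != set(DESCRIPTOR_COLUMNS):
            raise ValueError("QEDParams must cover exactly the eight QED properties")
        if set(self.weights) != set(DESCRIPTOR_COLUMNS):
            raise ValueError("weights must cover exactly the eight QED properties")
        w = np.array([self.weights[k] for k in DESCRIPTOR_COLUMNS], dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be finite, non-negative and not all zero")


def load_default_params(path: str | Path | None = None) -> QEDParams:
    """Load the bundled (or a user-supplied) QED parameter file."""
    if path is None:
        text = resources.files("formulanet").joinpath("data/qed_params.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    desir = {k: ADSCoefficients(**v) for k, v in raw["properties"].items()}
    return QEDParams(desirabilities=desir, weights={k: float(v) for k, v in raw["weights"].items()})


def compute_qed(record: CompoundRecord, params: QEDParams | None = None) -> float:
    """Weighted geometric mean of the eight desirabilities; sets ``record.qed``."""
    if params is None:
        params = load_default_params()
    log_sum = 0.0
    w_sum = 0.0
    for name in DESCRIPTOR_COLUMNS:
        x = record.descriptor(name)
        if not math.isfinite(x):
            raise ValueError(f"descriptor {name!r} of {record.compound_id!r} is missing or non-finite")
        d = max(params.desirabilities[name](x), DESIRABILITY_FLOOR)
        w = params.weights[name]
        log_sum += w * math.log(d)
        w_sum += w
    qed = math.exp(log_sum / w_sum)
    record.qed = qed
    return qed


def records_from_frame(df: pd.DataFrame) -> list[CompoundRecord]:
    """Build CompoundRecords from a descriptor DataFrame (see io.read_descriptors)."""
    out = []
    for row in df.itertuples(index=False):
        herbs = frozenset(str(getattr(row, "herb", "")).split(",")) - {"", "nan"}
        out.append(
            CompoundRecord(
                compound_id=str(row.compound_id),
                mw=float(row.mw), alogp=float(row.alogp),
                hba=int(row.hba), hbd=int(row.hbd), psa=float(row.psa),
                rotb=int(row.rotb), arom=int(row.arom), alerts=int(row.alerts),
                herb_ids=herbs,
            )
        )
    return out


def filter_druglike(
    records: list[CompoundRecord], cutoff: float = 0.25
) -> tuple[list[CompoundRecord], list[CompoundRecord]]:
    """Partition compounds into (retained, rejected) at ``qed > cutoff``."""
    for r in records:
        if r.qed is None:
            raise ValueError(f"compound {r.compound_id!r} has no QED; run compute_qed first")
    retained = [r for r in records if r.qed > cutoff]
    rejected = [r for r in records if r.qed <= cutoff]
    return retained, rejected


def pca_summary(records: list[CompoundRecord], n_components: int = 3):
    """Principal components of the z-scored eight-descriptor matrix.

    Returns ``(explained_variance_fractions, scores)`` where scores is a
    DataFrame of per-compound component coordinates. Descriptors are
    z-scored first; unscaled PCA on mixed-unit descriptors would be
    dominated by molecular mass.
    """
    if len(records) < 2:
        raise ValueError("PCA needs at least two compounds")
    if n_components > len(DESCRIPTOR_COLUMNS):
        raise ValueError(f"n_components must be <= {len(DESCRIPTOR_COLUMNS)}")
    x = np.array([[r.descriptor(c) for c in DESCRIPTOR_COLUMNS] for r in records], dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(z)
    frac = pca.explained_variance_ratio_
    score_df = pd.DataFrame(
        scores,
        index=[r.compound_id for r in records],
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frac, score_df


def qed_table(records: list[CompoundRecord]) -> pd.DataFrame:
    """Descriptor table plus the computed QED column, one row per compound."""
    rows = []
    for r in records:
        row = {"compound_id": r.compound_id, "herb": ",".join(sorted(r.herb_ids))}
        row.update({c: r.descriptor(c) for c in DESCRIPTOR_COLUMNS})
        row["qed"] = r.qed
        rows.append(row)
    return pd.DataFrame(rows)
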