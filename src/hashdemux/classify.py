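"""Joint droplet classification from per-HTO posterior probabilities.

Per-HTO MAP calls are combined under an independence assumption into a
joint probability that the whole call vector is correct; droplets whose
joint probability falls below the acceptance threshold ``p_acpt``
(default ``0.9 ** n``) are labeled ``uncertain``.  A single HTO (n=1,
tagged-vs-untagged pooling) is fully supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixture import hard_class

__all__ = [
    "DropletAssignment",
    "joint_probability",
    "default_acceptance",
    "classify_droplets",
    "assignments_frame",
]

LABELS = ("SSD", "MSM", "negative", "uncertain")


@dataclass(frozen=True)
class DropletAssignment:
    """Final call for one droplet."""

    droplet_id: str
    c_hat: tuple[int, ...]
    joint_prob: float
    label: str  # one of LABELS
    htos: tuple[str, ...]  # assigned HTO name(s); empty for negative/uncertain
    p_acpt: float

    @property
    def display_label(self) -> str:
        if self.label == "SSD":
            return f"SSD:{self.htos[0]}"
        if self.label == "MSM":
            return "MSM:" + ",".join(self.htos)
        return self.label


def joint_probability(posteriors_row, c_hat) -> float:
    """P(call vector is correct) = prod_j [p_j if called else 1 - p_j].

    Computed in log space to avoid underflow for many HTOs.
    """
    p = np.asarray(posteriors_row, dtype=float)
    c = np.asarray(c_hat)
    if p.shape != c.shape:
        raise ValueError("posteriors and call vector must have equal length")
    with np.errstate(divide="ignore"):
        logs = np.where(c == 1, np.log(p), np.log1p(-p))
    return float(np.exp(logs.sum()))


def default_acceptance(n: int) -> float:
    """Default acceptance threshold 0.9 ** n for n HTOs."""
    if n < 1:
        raise ValueError("need at least one HTO")
    return 0.9**n


def classify_droplets(
    posteriors,
    hto_names,
    droplet_ids=None,
    p_acpt: float | None = None,
) -> list[DropletAssignment]:
    """Turn an m x n posterior matrix into per-droplet assignments.

    The per-HTO call is the MAP class (positive iff posterior > 0.5); the
    label is SSD / MSM / negative by the number of positive calls when the
    joint probability reaches ``p_acpt``, and ``uncertain`` otherwise.
    """
    post = np.atleast_2d(np.asarray(posteriors, dtype=float))
    m, n = post.shape
    if np.any(post < 0) or np.any(post > 1):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    hto_names = [str(h) for h in hto_names]
    if len(hto_names) != n:
        raise ValueError("hto_names length must match posterior columns")
    if droplet_ids is None:
        droplet_ids = [str(i) for i in range(m)]
    if p_acpt is None:
        p_acpt = default_acceptance(n)
    if not (0 < p_acpt <= 1):
        raise ValueError(f"p_acpt must lie in (0, 1], got {p_acpt}")

    calls = hard_class(post)
    out: list[DropletAssignment] = []
    for i in range(m):
        c = calls[i]
        jp = joint_probability(post[i], c)
        k = int(c.sum())
        if jp < p_acpt:
            label, htos = "uncertain", ()
        elif k == 0:
            label, htos = "negative", ()
        elif k == 1:
            label = "SSD"
            htos = (hto_names[int(np.flatnonzero(c)[0])],)
        else:
            label = "MSM"
            htos = tuple(hto_names[j] for j in np.flatnonzero(c))
        out.append(
            DropletAssignment(
                droplet_id=str(droplet_ids[i]),
                c_hat=tuple(int(v) for v in c),
                joint_prob=jp,
                label=label,
                htos=htos,
                p_acpt=p_acpt,
            )
        )
    return out


def assignments_frame(
    assignments: list[DropletAssignment], posteriors=None, hto_names=None
) -> pd.DataFrame:
    """Tabulate assignments (stable column layout, suitable for TSV output).

    Columns: droplet_id, label, assigned_htos (comma-joined), joint_prob,
    then one ``posterior_<hto>`` column per HTO when posteriors are given.
    """
    df = pd.DataFrame(
        {
            "droplet_id": [a.droplet_id for a in assignments],
            "label": [a.label for a in assignments],
            "assigned_htos": [",".join(a.htos) for a in assignments],
            "joint_prob": [a.joint_prob for a in assignments],
        }
    )
    if posteriors is not None:
        post = np.atleast_2d(np.asarray(posteriors, dtype=float))
        names = hto_names if hto_names is not None else range(post.shape[1])
        for j, name in enumerate(names):
            df[f"posterior_{name}"] = post[:, j]
    return df
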