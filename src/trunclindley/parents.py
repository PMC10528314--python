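"""Parent distribution contract for the truncated Lindley-G composition.

A parent is any absolutely continuous law with cdf G, density g, and
quantile Q_G.  ``ParentModel`` bundles those callables together with the
support interval; :func:`ParentModel.from_scipy` adapts any frozen
``scipy.stats`` distribution, which is how the Weibull and uniform parents
used throughout the package are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import stats

__all__ = ["ParentModel", "weibull_parent", "uniform_parent"]


@dataclass(frozen=True)
class ParentModel:
    """Bundle of (cdf, pdf, logpdf, quantile, support) for a parent law G."""

    name: str
    cdf: Callable
    pdf: Callable
    logpdf: Callable
    ppf: Callable
    support: Tuple[float, float]
    #: differential (Shannon) entropy of the parent, if known in closed form;
    #: used only by the closed-form entropy shortcut.
    entropy: Optional[float] = field(default=None)

    @classmethod
    def from_scipy(cls, frozen, name: Optional[str] = None) -> "ParentModel":
        """Wrap a frozen ``scipy.stats`` continuous distribution."""
        a, b = frozen.support()
        try:
            ent = float(frozen.entropy())
        except Exception:  # pragma: no cover - exotic parents
            ent = None
        return cls(
            name=name or frozen.dist.name,
            cdf=frozen.cdf,
            pdf=frozen.pdf,
            logpdf=frozen.logpdf,
            ppf=frozen.ppf,
            support=(float(a), float(b)),
            entropy=ent,
        )


def weibull_parent(k: float, lam: float) -> ParentModel:
    """Two-parameter Weibull parent with shape ``k`` and scale ``lam``."""
    if k <= 0 or lam <= 0:
        raise ValueError("Weibull parent requires k > 0 and lam > 0")
    return ParentModel.from_scipy(
        stats.weibull_min(k, scale=lam), name=f"weibull(k={k:g}, lam={lam:g})"
    )


def uniform_parent() -> ParentModel:
    """Standard uniform parent; the composition then reduces to the unit law."""
    return ParentModel.from_scipy(stats.uniform(), name="uniform(0,1)")
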