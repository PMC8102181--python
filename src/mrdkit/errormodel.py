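"""Site- and mutation-specific background error model.

The model pools consensus pileups from control samples (samples with no
tracked mutation expected) and estimates, for every (target, position,
alternate allele) key, the background rate at which that exact change is
seen among consensus molecules:

    rate = (pooled alt count + pc) / (pooled depth + 2 * pc)

with a Jeffreys-like pseudocount ``pc = 0.5`` so that alleles never seen
in any control (in particular specific insertions and deletions) still
get a finite, conservative rate. An observed alternate count at an MRD
time point is scored with the one-sided upper-tail binomial test at that
key's rate; a beta-binomial tail with a pooled method-of-moments
overdispersion is available for panels with between-control variance.

Sites with zero pooled control depth are *unmodeled*: the caller must
refuse to call there rather than treat them as clean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats

from .consensus import PileupSet

MODEL_FORMAT_VERSION = 1


class UnmodeledSiteError(KeyError):
    """Raised when a (site, alt) key has no control coverage."""


def _alt_key(alt: str | tuple) -> str:
    """Canonical string key for an alternate allele class.

    ``"A".."T"`` for substitutions, ``("ins", seq)`` -> ``"ins:SEQ"``,
    ``("del", length)`` -> ``"del:LEN"``.
    """
    if isinstance(alt, tuple):
        kind, payload = alt
        return f"{kind}:{payload}"
    return alt


@dataclass
class SiteCounts:
    depth: int
    alts: dict[str, int]


class ErrorModel:
    """Pooled-control background error model with a ``fit`` interface.

    Fitted attributes (set by :meth:`fit`):

    sites_
        ``{(target, pos): SiteCounts}`` — pooled depth and pooled counts of
        every alternate allele observed in the controls.
    n_control_samples_
        number of control pileup sets pooled.
    """

    def __init__(self, pseudocount: float = 0.5, family: str = "binomial"):
        if family not in ("binomial", "betabinomial"):
            raise ValueError("family must be 'binomial' or 'betabinomial'")
        self.pseudocount = pseudocount
        self.family = family

    # ------------------------------------------------------------------ fit

    def fit(self, control_pileups: Iterable[PileupSet]) -> "ErrorModel":
        controls = list(control_pileups)
        if not controls:
            raise ValueError("at least one control sample is required")
        sites: dict[tuple[str, int], SiteCounts] = {}
        per_control: dict[tuple[str, int, str], list[tuple[int, int]]] = {}
        for ps in controls:
            for tp in ps:
                depth = tp.depth
                for i, refbase in enumerate(tp.ref):
                    pos = i + 1
                    key = (tp.target, pos)
                    sc = sites.setdefault(key, SiteCounts(0, {}))
                    d = int(depth[i])
                    sc.depth += d
                    for b, base in enumerate("ACGT"):
                        if base == refbase:
                            continue
                        cnt = int(tp.counts[b, i])
                        if cnt:
                            sc.alts[base] = sc.alts.get(base, 0) + cnt
                        per_control.setdefault((tp.target, pos, base), []).append(
                            (cnt, d)
                        )
                for (p, seq), cnt in tp.ins_events.items():
                    sc = sites.setdefault((tp.target, p), SiteCounts(0, {}))
                    k = _alt_key(("ins", seq))
                    sc.alts[k] = sc.alts.get(k, 0) + cnt
                for (p, ln), cnt in tp.del_events.items():
                    sc = sites.setdefault((tp.target, p), SiteCounts(0, {}))
                    k = _alt_key(("del", ln))
                    sc.alts[k] = sc.alts.get(k, 0) + cnt
        self.sites_ = sites
        self.n_control_samples_ = len(controls)
        self.overdispersion_ = (
            self._fit_overdispersion(per_control)
            if self.family == "betabinomial"
            else 0.0
        )
        return self

    @staticmethod
    def _fit_overdispersion(
        per_control: dict[tuple[str, int, str], list[tuple[int, int]]]
    ) -> float:
        """Pooled method-of-moments intra-class correlation across controls.

        Falls back to 0 (pure binomial) when the controls carry too few
        events to estimate between-sample variance.
        """
        num = den = 0.0
        for obs in per_control.values():
            if len(obs) < 2:
                continue
            counts = np.array([c for c, _ in obs], dtype=float)
            depths = np.array([d for _, d in obs], dtype=float)
            if counts.sum() < 2 or (depths > 0).sum() < 2:
                continue
            ok = depths > 0
            p = counts[ok] / depths[ok]
            pbar = counts[ok].sum() / depths[ok].sum()
            if pbar in (0.0, 1.0):
                continue
            var_within = pbar * (1 - pbar) / depths[ok]
            excess = np.maximum(p.var(ddof=1) - var_within.mean(), 0.0)
            num += excess
            den += pbar * (1 - pbar)
        if den == 0:
            return 0.0
        return float(min(num / den, 0.99))

    # ---------------------------------------------------------------- query

    def _site(self, target: str, pos: int) -> SiteCounts:
        try:
            sc = self.sites_[(target, pos)]
        except (AttributeError, KeyError):
            raise UnmodeledSiteError(
                f"site {target}:{pos} absent from the fitted model"
            ) from None
        if sc.depth == 0:
            raise UnmodeledSiteError(
                f"site {target}:{pos} has zero control depth (unmodeled)"
            )
        return sc

    def is_modeled(self, target: str, pos: int) -> bool:
        sc = getattr(self, "sites_", {}).get((target, pos))
        return sc is not None and sc.depth > 0

    def rate(self, target: str, pos: int, alt: str | tuple) -> float:
        """Background rate for a (site, alt) key; pseudocount-only for alt
        classes never observed in the controls."""
        sc = self._site(target, pos)
        count = sc.alts.get(_alt_key(alt), 0)
        return (count + self.pseudocount) / (sc.depth + 2 * self.pseudocount)

    def site_pvalue(
        self, target: str, pos: int, alt: str | tuple, alt_count: int, depth: int
    ) -> float:
        """One-sided upper-tail P(X >= alt_count) under the background rate."""
        if alt_count > depth:
            raise ValueError("alt_count cannot exceed depth")
        if alt_count < 0 or depth <= 0:
            raise ValueError("alt_count >= 0 and depth > 0 required")
        r = self.rate(target, pos, alt)
        if self.family == "betabinomial" and self.overdispersion_ > 0:
            rho = self.overdispersion_
            s = (1 - rho) / rho
            p = stats.betabinom.sf(alt_count - 1, depth, r * s, (1 - r) * s)
        else:
            p = stats.binom.sf(alt_count - 1, depth, r)
        return float(min(max(p, np.nextafter(0, 1)), 1.0))

    # -------------------------------------------------------------- persist

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "family": self.family,
            "pseudocount": self.pseudocount,
            "n_control_samples": self.n_control_samples_,
            "overdispersion": self.overdispersion_,
            "created": date.today().isoformat(),
            "sites": [
                {
                    "target": t,
                    "pos": p,
                    "depth": sc.depth,
                    "alts": sc.alts,
                }
                for (t, p), sc in sorted(self.sites_.items())
            ],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "ErrorModel":
        with open(path) as handle:
            payload = json.load(handle)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported error-model format version")
        model = cls(pseudocount=payload["pseudocount"], family=payload["family"])
        model.sites_ = {
            (s["target"], s["pos"]): SiteCounts(s["depth"], dict(s["alts"]))
            for s in payload["sites"]
        }
        model.n_control_samples_ = payload["n_control_samples"]
        model.overdispersion_ = payload["overdispersion"]
        return model


def fit_error_model(
    control_pileups: Iterable[PileupSet],
    pseudocount: float = 0.5,
    family: str = "binomial",
) -> ErrorModel:
    """Convenience wrapper: fit an :class:`ErrorModel` on control pileups."""
    return ErrorModel(pseudocount=pseudocount, family=family).fit(control_pileups)
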