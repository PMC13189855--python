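"""Combined quality scores from the raw network outputs.

The network emits three global fold estimates (bb-lDDT, GDT-TS, GDT-HA),
three global interface estimates (iLDDT, IPS, ICS) and two estimates (IPS,
ICS) per protein-RNA interface. Averaging — the same operation the L1
training loss decomposes over — combines them into the published score set:

fold     mean of the three fold estimates
iface    mean of the three interface estimates
merged   mean of fold and iface
perif[i] mean of the two per-interface estimates of interface i
perif_g[i] mean of perif[i] and iface
rp       grand mean of all per-interface estimates
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import QAOutput

__all__ = ["CombinedScores", "combined_scores"]


@dataclass
class CombinedScores:
    fold: float
    iface: float
    merged: float
    rp: float  # NaN when the model has no protein-RNA interface
    per_if: list[tuple[tuple[str, str], float, float]] = field(default_factory=list)
    # per_if entries: (interface, perif, perif_g)

    def as_dict(self) -> dict[str, float]:
        out = {
            "fold": self.fold,
            "iface": self.iface,
            "merged": self.merged,
            "rp": self.rp,
        }
        for (pc, rc), perif, perif_g in self.per_if:
            out[f"perif[{pc}:{rc}]"] = perif
            out[f"perif_g[{pc}:{rc}]"] = perif_g
        return out


def combined_scores(out: QAOutput) -> CombinedScores:
    """Average the raw predictions into the six combined scores.

    With zero interfaces the per-interface list is empty and rp is NaN;
    global scores are still emitted.
    """
    out = out.detach()
    fold = float(np.mean(out.fold))
    iface = float(np.mean(out.iface))
    merged = (fold + iface) / 2.0
    per_if = []
    all_p: list[float] = []
    for pair, p in out.per_interface:
        perif = float(np.mean(p))
        per_if.append((pair, perif, (perif + iface) / 2.0))
        all_p.extend(float(v) for v in p)
    rp = float(np.mean(all_p)) if all_p else float("nan")
    return CombinedScores(fold=fold, iface=iface, merged=merged, rp=rp, per_if=per_if)
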