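"""Threshold calibration for the LARKS/zipper screen.

The energy function is in arbitrary units, so the acceptance thresholds are
calibrated quantities, fixed against two control sets and shipped as
versioned data (``data/calibration.json``):

* ``tau_L`` (LARKS acceptance) — positives are the wild-type low-complexity
  segments known to form kinked fibrils (the three template name-sakes plus
  the KRT8 head-domain 6-mers); negatives are scrambled charged/bulky
  sequences that no kinked backbone should accommodate.  ``tau_L`` sits a
  quarter of the way from the worst positive to the best negative.
* ``tau_Z`` (absolute zipper viability) — the largest mutant-register energy
  among control conversions that improve on their wild type, plus a 10%
  margin: every control's conversion-capable register is zipper-viable.
* ``delta_max`` — 80% of the weakest (least negative) control conversion's
  delta: a conversion call requires an energy decrease commensurate with the
  weakest experimentally confirmed control, not merely any decrease.

Rerun with ``python -m larkszip.calibrate`` (or ``larkszip calibrate``) to
regenerate the file; the procedure is deterministic.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .templates import load_builtin_templates
from .threading import EnergyWeights, thread_window

#: wild-type kinked-segment positives (template name-sakes + KRT8 6-mers)
LARKS_POSITIVES = [
    "STGGYS", "SYSGYS", "GYNGFG",
    "GGYGGA", "GYGGAS", "SGMGGI", "GMGGIT",
]
#: scrambled charged/bulky negatives
LARKS_NEGATIVES = [
    "WWWWWW", "KWEWRF", "REKDKE", "WRWDWK",
    "KRKRKR", "WFYWFY", "YKEWRY", "EDEDED",
]
#: control conversions: (wild-type windows, mutant windows) per variant
ZIPPER_CONTROLS = {
    "KRT8_G62C": (("SGMGGI", "GMGGIT"), ("SGMGCI", "GMGCIT")),
    "KRT8_G55A": (("GGYGGA", "GYGGAS"), ("GGYAGA", "GYAGAS")),
    "KRT8_Y54H": (("GGYGGA", "GYGGAS"), ("GGHGGA", "GHGGAS")),
}

TAU_L_FRACTION = 0.25
TAU_Z_MARGIN_FRACTION = 0.10
DELTA_MAX_FRACTION = 0.80


def calibrate(weights: EnergyWeights | None = None) -> dict:
    """Compute thresholds from the control sets; returns the calibration dict."""
    weights = weights or EnergyWeights()
    templates = load_builtin_templates()
    larks = [t for t in templates if t.category == "LARKS"]
    zipper = next(t for t in templates if t.category == "zipper")

    def e_larks(seq: str) -> float:
        return min(thread_window(seq, t, weights=weights)[1] for t in larks)

    def e_zip(seq: str) -> float:
        return thread_window(seq, zipper, weights=weights)[1]

    pos = {s: e_larks(s) for s in LARKS_POSITIVES}
    neg = {s: e_larks(s) for s in LARKS_NEGATIVES}
    pos_max = max(pos.values())
    neg_min = min(neg.values())
    if neg_min <= pos_max:
        raise RuntimeError(
            "calibration controls do not separate: "
            f"worst positive {pos_max:.1f} >= best negative {neg_min:.1f}")
    tau_l = pos_max + TAU_L_FRACTION * (neg_min - pos_max)

    selected = {}
    for name, (wt_windows, mut_windows) in ZIPPER_CONTROLS.items():
        deltas = [e_zip(m) - e_zip(w) for w, m in zip(wt_windows, mut_windows)]
        improving = [i for i, d in enumerate(deltas) if d < 0]
        # the control's conversion-capable register: the zipper-improving one
        # with the lowest mutant energy
        k = min(improving, key=lambda i: e_zip(mut_windows[i]))
        selected[name] = {"window": mut_windows[k], "e_zip_mut": e_zip(mut_windows[k]),
                          "delta": deltas[k]}
    worst = max(v["e_zip_mut"] for v in selected.values())
    tau_z = worst + TAU_Z_MARGIN_FRACTION * abs(worst)
    weakest_delta = max(v["delta"] for v in selected.values())
    delta_max = DELTA_MAX_FRACTION * weakest_delta

    return {
        "tau_L": tau_l,
        "tau_Z": tau_z,
        "delta_max": delta_max,
        "weights": {"w_rep": weights.w_rep, "w_att": weights.w_att,
                    "w_solv": weights.w_solv, "w_hb": weights.w_hb},
        "controls": {
            "larks_positives": {k: round(v, 4) for k, v in pos.items()},
            "larks_negatives": {k: round(v, 4) for k, v in neg.items()},
            "zipper_selected": {k: {kk: (round(vv, 4) if isinstance(vv, float) else vv)
                                    for kk, vv in v.items()}
                                for k, v in selected.items()},
        },
    }


def shipped_calibration() -> dict:
    """The calibration shipped with the package."""
    text = resources.files("larkszip.data").joinpath("calibration.json").read_text()
    return json.loads(text)


def write_calibration(path: str | Path | None = None) -> dict:
    """Recompute the calibration and write it as JSON (default: package data)."""
    cal = calibrate()
    if path is None:
        path = Path(__file__).parent / "data" / "calibration.json"
    Path(path).write_text(json.dumps(cal, indent=1))
    return cal


if __name__ == "__main__":
    cal = write_calibration()
    print(json.dumps({k: cal[k] for k in ("tau_L", "tau_Z", "delta_max")}, indent=1))
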