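#!/usr/bin/env python
"""Equilibria and stability of both models at the canonical rates.

Finds: the estrogen-free model admits four candidate steady states, of
which the tumor-free state (2.333, 0, 1.379) and the tissue-removal
state (0, 0, 1.379) are genuine fixed points; the tumor-free state is
locally AND globally stable at the canonical rates (resistance
coefficient s*gamma2/mu = 1.241 exceeds the tumor growth rate 0.98),
while every host-free state is unstable.  With an estrogen source the
published tumor-free closed form no longer zeroes the vector field
(the conversion influx sigma2*H*E persists at T = 0), a coexisting
fixed point opens up instead, and global stability is lost.
"""

import json
from pathlib import Path

from bcdyn import DEFAULT_ESTROGEN_PARAMS, TABLE1_PARAMS
from bcdyn.io import equilibria_report, write_json

OUT = Path(__file__).resolve().parent.parent / "results"


def describe(report: dict) -> None:
    print(f"\n== {report['model']} model ==")
    for e in report["equilibria"]:
        state = ", ".join(f"{x:.6g}" for x in e["state"])
        stab = e.get("stability", {}).get("classification", "n/a")
        print(
            f"  {e['label']:<11} ({state})  feasible={e['feasible']}"
            f"  residual={e['residual']:.2e}  local={stab}"
        )
    g = report["global"]
    print(f"  global verdict: {g['global_verdict']} (A={g['A']:.4f}, G*={g['Gstar']:.4f})")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    for params, name in (
        (TABLE1_PARAMS, "estrogen_free"),
        (DEFAULT_ESTROGEN_PARAMS, "estrogen"),
    ):
        report = equilibria_report(params)
        write_json(OUT / f"equilibria_{name}.json", report)
        describe(report)
    print(f"\nwrote {OUT}/equilibria_*.json")


if __name__ == "__main__":
    main()
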