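#!/usr/bin/env python
"""Generate the synthetic study inputs: a 20-structure cystine-dimer corpus,
a single-Cys monomer decorated with Trp/Tyr, and one noisy curve of each
measurement type. Everything lands under results/synthetic/ with truth
sidecars so later stages can be checked against known ground truth."""

import json
from pathlib import Path

import pandas as pd

import cysdimer.synthetic_data as syn
from cysdimer.structio import write_pdb

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    paths, sidecar = syn.make_library_corpus(20, "bimodal", seed=SEED,
                                             out_dir=OUT / "corpus")
    print(f"corpus: {len(paths)} two-chain dimers, chi3 drawn near +-90 deg "
          f"-> {OUT/'corpus'}")

    mono = syn.make_protomer(12, 6, seed=SEED, aromatics={3: "TRP", 9: "TYR"})
    write_pdb(mono, OUT / "monomer.pdb")
    print("monomer: 12-residue helical protomer, Cys6, Trp3/Tyr9")

    curves, truth = syn.make_hemolysis_curves(noise_sd=0.02, seed=SEED)
    for i, c in enumerate(curves):
        pd.DataFrame({"time_min": c.times, "od600": c.turbidity}).to_csv(
            OUT / f"hemolysis_{i:02d}.csv", index=False)
    (OUT / "hemolysis_truth.json").write_text(json.dumps(truth, indent=1))

    for name, gen in (
        ("melting", lambda: syn.make_melting_curve(noise_sd=0.02, seed=SEED)),
        ("quench", lambda: syn.make_quench_series(noise_sd=0.02, seed=SEED)),
        ("maldi", lambda: syn.make_maldi_peaks(seed=SEED)),
    ):
        obj, truth = gen()
        (OUT / f"{name}_truth.json").write_text(json.dumps(truth, indent=1))
    print(f"curves + truth sidecars -> {OUT}")


if __name__ == "__main__":
    main()
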