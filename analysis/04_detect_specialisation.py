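#!/usr/bin/env python
"""Detect emerging functional specialisation in the synthetic recording.

Fits the specialisation GLM per electrode for each source — the interaction
of a centred source-presence indicator with an 8-component DCT time basis,
against stimulation, drift and other-source confounds — and reports the
F-statistic map on the 8x8 grid, which electrodes pass the F > 80
threshold, and whether the max-F electrodes coincide with the electrodes
the generator actually specialised.  The same analysis against surrogate
(epoch-permuted) sources serves as the null control.

Writes results/specialisation_f.tsv and results/fmap_source{1,2}.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from meabayes import glm, study

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0, threshold: float = 80.0) -> None:
    run = study.closed_loop(seed=seed, n_sessions=8, epochs_per_session=256)
    OUT.mkdir(exist_ok=True)
    rows = []
    for source in (0, 1):
        fits = run.fits["true", source]
        surr = run.fits["surrogate", source]
        fmap = glm.f_map(fits)
        np.savetxt(OUT / f"fmap_source{source + 1}.csv", fmap,
                   delimiter=",", fmt="%.4g")
        fvals = np.array([f.F for f in fits])
        passing = np.flatnonzero(fvals > threshold)
        best = int(np.argmax(fvals))
        print(f"source {source + 1}: max F {fvals[best]:.1f} at electrode {best} "
              f"(planted: {sorted(run.planted[source])})")
        print(f"  electrodes with F > {threshold:g}: {passing.tolist()}")
        print(f"  surrogate max F: {max(f.F for f in surr):.1f} "
              "(null control; nothing should pass)")
        for e, (f, fs) in enumerate(zip(fits, surr)):
            rows.append({"source": source + 1, "electrode": e,
                         "F": round(f.F, 3), "p": f.pvalue,
                         "F_surrogate": round(fs.F, 3),
                         "planted": e in run.planted[source]})
    pd.DataFrame(rows).to_csv(OUT / "specialisation_f.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'specialisation_f.tsv'} and F maps")


if __name__ == "__main__":
    main()
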