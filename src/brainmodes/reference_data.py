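"""Published natural frequencies used as printed inputs.

Two tables of frequencies (Hz) for the first 25 head/brain modes:

* ``LITERATURE_FREQUENCIES_HZ`` — the head-and-neck finite-element
  reference study (Tse et al.) against which the multi-compartment model
  was benchmarked;
* ``STUDY_BC_FREQUENCIES_HZ`` — the multi-compartment study's own values
  under the skull-base, neck, spine and fMRI-immobilization boundary
  conditions.

These numbers are inputs to NRFD worked examples (the percentage
differences quoted alongside them), not quantities this package
re-simulates: they belong to cluster-scale anatomical meshes.
"""

from __future__ import annotations

__all__ = ["LITERATURE_FREQUENCIES_HZ", "STUDY_BC_FREQUENCIES_HZ",
           "nrfd_worked_examples"]

#: Tse et al. head-neck FE model, mode number -> frequency (Hz)
LITERATURE_FREQUENCIES_HZ: dict[int, float] = {
    1: 33.57,
    2: 62.89,
    5: 221.51,
    9: 256.40,
    13: 283.24,
    25: 356.39,
}

#: Multi-compartment head model, boundary condition -> mode -> frequency (Hz)
STUDY_BC_FREQUENCIES_HZ: dict[str, dict[int, float]] = {
    "skull": {1: 24.17, 2: 33.33, 3: 83.08, 13: 156.57, 25: 188.97},
    "neck": {1: 10.57, 2: 11.12, 3: 23.93, 13: 157.37, 25: 189.16},
    "spine": {1: 1.78, 2: 1.79, 3: 9.90, 5: 20.45, 9: 137.42,
              13: 157.20, 25: 189.07},
    "fmri": {9: 129.04, 13: 156.58, 25: 188.98},
}


def nrfd_worked_examples() -> dict[str, dict]:
    """The three NRFD worked examples computable from the printed tables.

    Returns a mapping of short names to the frequency pair (reference
    first) feeding ``compare.nrfd``:

    * ``skull_vs_spine_mode2`` — mode-2 frequency under skull fixation vs
      under spine fixation;
    * ``literature_vs_spine_mode5`` — literature mode 5 vs the spine
      condition;
    * ``literature_vs_fmri_mode25`` — literature mode 25 vs the fMRI
      condition.
    """
    return {
        "skull_vs_spine_mode2": {
            "f_ref": STUDY_BC_FREQUENCIES_HZ["skull"][2],
            "f_val": STUDY_BC_FREQUENCIES_HZ["spine"][2],
        },
        "literature_vs_spine_mode5": {
            "f_ref": LITERATURE_FREQUENCIES_HZ[5],
            "f_val": STUDY_BC_FREQUENCIES_HZ["spine"][5],
        },
        "literature_vs_fmri_mode25": {
            "f_ref": LITERATURE_FREQUENCIES_HZ[25],
            "f_val": STUDY_BC_FREQUENCIES_HZ["fmri"][25],
        },
    }
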