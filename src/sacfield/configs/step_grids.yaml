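# Level sets of the controlled-variability parameter grids, per species and
# modification step.  Each step lists only the attributes it changes; steps
# are composed cumulatively (step 2 includes step 1's changes, and so on).
#
# Attribute naming: <input>_<kind> with inputs
#   vt = visual transient (1)      am = automated motor (2)
#   af = automated fixation (3)    vm = voluntary motor (4)
#   vf = voluntary fixation (5)    vp = voluntary preparation (6)
#   ig = inhibitory gate (7)       pi = peripheral inhibition (8)
# and kinds onset (ms), ror (% of MaxVal per ms), maxval (drive units).
# "internal_onset" is the jointly drawn onset delay (ms, relative to target
# onset) shared by inputs 4-8.
#
# Values quoted from the source study's modification narrative are used
# verbatim; cells hidden by the print rendering of its settings table are
# reconstructed to satisfy the stated attribute counts (marmoset final
# grid: ten 3-level + three 4-level attributes; human final grid: thirteen
# 3-level attributes) and are editable here.

marmoset:
  step1:
    vt_onset: [50]
    vt_ror: [10, 15]
    vt_maxval: [8]
    am_onset: [60, 75, 90]
    am_ror: [4, 6, 8]
    am_maxval: [4, 6, 8]
    af_onset: [60, 75, 90]
    af_ror: [10]
    af_maxval: [6]
    internal_onset: [75, 100, 125]
    vm_ror: [5, 10, 15]
    vf_ror: [10]
    vf_maxval: [4, 6, 8]
    vp_maxval: [4, 6, 8]
    ig_ror: [5, 10, 15]
    ig_maxval: [4, 6, 8]
    pi_ror: [5, 10, 15]
    pi_maxval: [4, 6, 8]
  step2:
    # faster visual transduction and earlier automated motor command,
    # plus augmented disinhibition / weakened fixation (an added low
    # MaxVal level of 2 for the two inhibitory inputs and voluntary fixation)
    vt_onset: [20]
    vt_ror: [10, 15, 20]
    am_onset: [30, 45, 60]
    am_ror: [6, 8, 10]
    af_onset: [30, 45, 60]
    vf_maxval: [2, 4, 6, 8]
    ig_maxval: [2, 4, 6, 8]
    pi_maxval: [2, 4, 6, 8]
  step3:
    # variable (occasionally sluggish) disinhibition and voluntary build-up
    ig_ror: [1, 10, 20]
    pi_ror: [1, 10, 20]
    vm_ror: [1, 10, 20]
    af_ror: [8]
    vf_ror: [8]

human:
  step1:
    vt_onset: [50]
    vt_ror: [10, 15]
    vt_maxval: [8]
    am_onset: [60]
    am_ror: [4, 6, 8]
    am_maxval: [6]
    af_onset: [60, 75, 90]
    af_ror: [10]
    af_maxval: [6]
    internal_onset: [100, 115, 130]
    vm_ror: [5, 10, 15]
    vf_ror: [10]
    vf_maxval: [4, 6, 8]
    vp_maxval: [4, 6, 8]
    ig_ror: [5, 10, 15]
    ig_maxval: [4, 6, 8]
    pi_ror: [5, 10, 15]
    pi_maxval: [4, 6, 8]
  step2:
    # visual-transient and automated-motor adjustments kept consistent
    # with the marmoset treatment
    vt_ror: [10, 15, 20]
    am_onset: [60, 75, 90]
    am_maxval: [4, 6, 8]
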