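# Registry of the 13 missense-deleteriousness predictors whose scores the
# pathogenicity cascade aggregates.  The cascade never runs these tools; it
# only converts user-supplied scores to deleterious/benign verdicts.
#
# direction: "higher" means scores at or above the threshold are called
# deleterious; "lower" means scores at or below it are.  The thresholds are
# package defaults on each tool's published score scale (synthetic stand-in
# defaults; override with your own registry file when you have calibrated
# cut-offs).
tools:
  PolyPhen2:        {threshold: 0.5,   direction: higher}
  SIFT:             {threshold: 0.05,  direction: lower}
  VEST:             {threshold: 0.5,   direction: higher}
  Mitoclass.1:      {threshold: 0.5,   direction: higher}   # categorical: 1 = damaging
  SNPdryad:         {threshold: 0.5,   direction: higher}
  AlphaMissense:    {threshold: 0.564, direction: higher}
  CADD:             {threshold: 20.0,  direction: higher}
  PROVEAN:          {threshold: -2.5,  direction: lower}
  MutationAssessor: {threshold: 1.9,   direction: higher}
  EFIN:             {threshold: 0.6,   direction: higher}
  MLC:              {threshold: 0.5,   direction: higher}
  MutationTaster:   {threshold: 0.5,   direction: higher}
  FATHMM:           {threshold: -1.5,  direction: lower}
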