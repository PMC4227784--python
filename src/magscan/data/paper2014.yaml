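# Scanning-model parameter preset fitted to the printed constraint set
# (see docs/methods.md, 'Parameter fitting'). Regenerate with:
#   magscan fit-model --seed 0 --out paper2014.yaml
contexts:
  adequate:
    ceil: 0.880874012149905
    floor: 0.2999994156402413
    midpoint: 0.8990506561942885
    steepness: 0.008000000002109542
  strong:
    ceil: 0.7608997600166723
    floor: 0.7608997600166723
    midpoint: 0.8
    steepness: 1.0
  weak:
    ceil: 0.5
    floor: 0.02
    midpoint: 1.0
    steepness: 0.15
loading_amp: 100.0
loading_center:
- 0.871319241044056
- 0.0015734477762056331
loading_width: 0.2021722932092774
reinit_prob: 0.02000000000059611
uncapped_scale: 0.05
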