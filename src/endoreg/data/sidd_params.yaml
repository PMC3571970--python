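# Default energetics for the stress-induced duplex destabilization (SIDD)
# model at 37 C.  Strand-separation free energies follow the classic
# copolymeric values (b_GC > b_AT); the nucleation term is the effective
# cost of creating the two helix/coil junctions of one denatured run; the
# torsional stiffness is the effective quadratic coefficient for the
# residual superhelicity of the default 250 bp analysis window.
name: sidd
sigma: -0.055            # superhelical density (dimensionless)
temperature_K: 310.0
nucleation_energy_a: 12.0        # kcal/mol per denatured run
separation_energy:
  AT: 0.255              # kcal/mol per open A:T pair
  GC: 1.301              # kcal/mol per open G:C pair
torsional_stiffness_K: 9.0       # kcal/mol per (linking difference, turns)^2
helical_repeat_h: 10.5   # bp/turn
energy_threshold_theta: 12.0     # kcal/mol above the minimum-energy state
max_run_length: 150      # bp per denatured run
window_bp: 250           # analysis window for long sequences
flank_bp: 50             # discarded window flanks
max_runs: 2              # simultaneous denatured runs considered
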