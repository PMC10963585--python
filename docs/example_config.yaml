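# Example scenario configuration for `lobulefem simulate`.
# Omitted keys fall back to the package defaults (see ScenarioConfig).
geometry: single_lobule          # or group7
bc_preset: undisturbed           # outflow_obstruction / obstruction_with_drainage
p_in: 133.0                      # Pa (1 mmHg over the outflow gauge)
p_out: 0.0
inflow_conc:
  FFA: 3.0                       # mmol/l; 0.2 gives the periportal pattern
  Ox: 0.091
t_end: 1610.0
dt: 10.0
output_times: [0.0, 200.0, 500.0, 1000.0, 1610.0]
circumradius: 5.0e-4             # m
# target_edge_length: 3.125e-5   # default: circumradius / 16
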