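# Default configuration for the zonal schooling model.
# Keys accept either the long field names of SimulationParams or the
# conventional symbols (N, U, zr, zl, za, alpha, theta_max, sigma, dt, T).
simulation:
  N: 100            # number of fish
  U: 3.0            # swimming speed (body lengths per time unit)
  zr: 1.0           # repulsion radius (body lengths)
  zl: 2.0           # alignment radius
  za: 10.0          # attraction radius
  alpha: 270.0      # field of view (degrees); blind cone of 90 deg behind
  theta_max: 40.0   # maximum turning rate (degrees per time unit)
  sigma: 0.01       # Cartesian heading-noise s.d. per step
  dt: 0.1           # integration step (time units)
  T: 500.0          # total simulated duration
  seed: 0
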