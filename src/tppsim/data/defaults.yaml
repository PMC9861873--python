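# Packaged default parameter sets.
#
# Provenance: layer geometry and thermophysical constants below are
# literature-typical stand-ins assembled from the classical protective
# clothing / bioheat modelling lineage (Torvi & Dale-style skin and
# Nomex-type shell with Beer's-law in-depth absorption; light three-layer
# ensembles as used in multi-layer garment models by Su et al. and Ghazy &
# Bergstrom).  They are NOT measurements shipped with this package; any
# value can be overridden in a scenario file.  Strict SI units throughout.

fabric:
  three_layer_nomex:
    - name: shell
      thickness: 0.0006        # m
      density: 313.0           # kg/m^3
      specific_heat: 1300.0    # J/(kg K)
      conductivity: nomex_shell  # temperature-dependent fibre/air blend
      emissivity: 0.9
      transmissivity: 0.044    # fixes the Beer extinction coefficient
    - name: moisture_barrier
      thickness: 0.00055
      density: 330.0
      specific_heat: 1380.0
      conductivity: 0.033      # W/(m K), constant
    - name: thermal_liner
      thickness: 0.0026
      density: 75.0
      specific_heat: 1300.0
      conductivity: 0.038
      emissivity: 0.9          # back face, toward the gap enclosure

  # Stand-in for the thin three-layer ensembles used in flash-fire (TPP
  # bench test, ~83 kW/m^2) modelling studies: light shell, membrane-type
  # moisture barrier, thin needled liner.  Synthetic values assembled from
  # typical published figures, not a measured garment.
  flash_fire_ensemble:
    - name: shell
      thickness: 0.00058
      density: 313.0
      specific_heat: 1200.0
      conductivity: nomex_shell
      emissivity: 0.9
      transmissivity: 0.044
    - name: moisture_barrier
      thickness: 0.00011
      density: 700.0
      specific_heat: 1500.0
      conductivity: 0.12       # dense polymer membrane, thin
    - name: thermal_liner
      thickness: 0.0015
      density: 70.0
      specific_heat: 1300.0
      conductivity: 0.038
      emissivity: 0.9

skin:
  torvi_three_layer:
    basal_temperature: 306.65            # K, pinned deep boundary
    surface_initial_temperature: 305.65  # K
    emissivity: 0.94
    layers:
      - name: epidermis
        thickness: 0.00008
        density: 1200.0
        specific_heat: 3598.0
        conductivity: 0.255
      - name: dermis
        thickness: 0.002
        density: 1200.0
        specific_heat: 3222.0
        conductivity: 0.523
      - name: subcutaneous
        thickness: 0.01
        density: 1000.0
        specific_heat: 2760.0
        conductivity: 0.167

air:
  density: 1.177          # kg/m^3 (gap air, ~300 K)
  specific_heat: 1006.0   # J/(kg K)

convection:
  g: 9.81
  Pr: 0.707
  L_f: 0.1                # m, characteristic plate length
  nu_ref: 1.589e-5        # m^2/s at 300 K; film values scale as (T/300)^1.7

gap_radiation:
  eps_therm: 0.9
  eps_skin: 0.94
  F_therm_skin: 1.0
  kappa_air: 5.0          # 1/m

geometry:
  # The source/body disc radii are not physical measurements: they are
  # backed out (jointly with the calibrated source temperature) so that the
  # nominal exposure level is met at the start distance AND the approach /
  # retreat dynamics sit in the regime where the time to 2nd degree burn is
  # minimized at medium body-movement speed.  Smaller radii make the
  # close-approach flux spike dominate every speed level.
  r_hs: 1.5               # m, heat-source disc radius
  r_shell: 1.5            # m, clothed-body disc radius
  x_max: 0.3              # m
  x_min: 5.0e-5           # m
  T_amb: 300.0            # K
  eps_hs: 0.9
  eps_g: 0.02             # hot-gas emissivity screening re-radiation

exposure_levels:
  low_level: 8500.0       # W/m^2 nominal incident flux at x_max, cold start
  flash_fire: 83000.0

gap_motion:
  x0: 0.003               # m, mean microenvironment thickness
  floor: 1.0e-4           # m, minimum thickness (near-contact)

solver:
  dt: 0.1                 # s
  dx: 5.0e-6              # m
  duration: 300.0         # s

speed_levels:             # arrival time at x_min (s) and gap frequency (1/s)
  low:    {arrival_time: 300.0, frequency: 0.25, trajectory: enter}
  medium: {arrival_time: 100.0, frequency: 0.5,  trajectory: enter_exit_hold}
  high:   {arrival_time: 60.0,  frequency: 1.0,  trajectory: enter_exit_hold}
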