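"""Physical constants used throughout (strict SI internally)."""

#: Elementary charge, C (CODATA 2018 exact).
ELEMENTARY_CHARGE = 1.602176634e-19

#: Unified atomic mass unit, kg (CODATA 2018).
ATOMIC_MASS_UNIT = 1.66053906660e-27

#: Interface-unit conversion factors. Internal code is strict SI (kg, m, s,
#: V/m); nanoseconds, millimetres and kilovolts appear only at interfaces.
NS = 1e-9
MM = 1e-3
KV = 1e3
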