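"""The MiM2 motor program after a single odor detection.

One detection at t = 0 triggers a ~0.5 s straight surge (speed K_v(f),
slight turn omega0 toward the detected side), then zigzag turns whose
direction alternates with the turn counter N, saturating into looping.
"""

from surgecast.controllers import MiM2Params, MiM2State, mim2_command, turn_number

params = MiM2Params()
state = MiM2State(t_d=0.0, rd0=+1, f=0.4, matched=True)

print("  tau(s)    v(mm/s)  omega(rad/s)   N   phase")
for tau in (0.0, 0.25, 0.49, 0.51, 1.0, 2.0, 4.0, 8.0):
    cmd = mim2_command(state, tau, params)
    n = turn_number(tau)
    phase = "surge" if tau < params.beta else ("zigzag" if n < 3 else "looping")
    print(f"  {tau:5.2f}   {cmd.v:8.3f}   {cmd.omega:+10.3f}  {n:2d}   {phase}")

print()
print("Reading: the agent dashes ahead for 0.5 s after the hit (v ~ K_v(0.4)")
print("= 15.04 mm/s decaying as exp(-tau)), then stops translating and turns")
print("toward the detected side (+ = rightward), alternating sides as N grows,")
print("until N saturates at 3 and the turning becomes one-directional looping.")
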