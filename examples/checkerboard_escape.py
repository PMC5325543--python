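"""Checkerboard escape: spatial sorting under patterned illumination.

Simulates the 17-min checkerboard experiment (580-um squares) for a naive
(cycle-1) and an adapted (cycle-4) population and compares how well cells
avoid the illuminated area I.
"""

from phototrace.pipeline import run_experiment

for cycle in (1, 4):
    res = run_experiment("B", cycle=cycle, n_cells=200, seed=1,
                         snapshot_at_board_end=True, duration=1040.0)
    s = res["separation"]
    print(f"cycle {cycle}:  separation ratio S = TM_II/(TM_I+TM_II) = {s.s_on:.2f}"
          f"   cells in illuminated area I at 17 min: {res['occupancy_I']*100:.0f}%")

print()
print("A naive population is captured by the bright squares (rotating cells")
print("cannot leave), so S stays near or below 0.5; the adapted population's")
print("run/tumble response deflects cells at square boundaries, shifting both")
print("the traces and the cells themselves toward the dark area II.")
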