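"""A steady-state beat of the baseline (male endocardial) cell at 1 Hz.

Prints the standard electrophysiology / calcium / contraction biomarkers:
APD90 (ms), resting potential (mV), calcium-transient diastolic level and
amplitude (mM), time to peak and duration (ms), peak active tension (kPa)
and diastolic SR calcium (mM).
"""

from myocyte import build_parameters, pace
from myocyte.biomarkers import beat_biomarkers, clearance_fractions
from myocyte.snapshots import steady_state

p = build_parameters("male")
trace = pace(p, bcl=1000.0, n_beats=50, y0=steady_state("male", 1.0),
             record_from=49)

b = beat_biomarkers(trace)
print(f"APD90            {b.apd90:8.1f} ms")
print(f"resting V        {b.v_rest:8.1f} mV")
print(f"CaT diastolic    {b.cat_diastolic * 1e6:8.1f} nM")
print(f"CaT amplitude    {b.cat_amplitude * 1e6:8.1f} nM")
print(f"CaT time-to-peak {b.cat_ttp:8.1f} ms")
print(f"CaTD90           {b.catd90:8.1f} ms")
print(f"peak tension     {b.tension_peak:8.1f} kPa")
print(f"SR Ca (diast.)   {b.ca_sr_diastolic:8.2f} mM")

cf = clearance_fractions(trace)
print("\ncytosolic Ca removal during the transient decay:")
print(f"  SERCA {100 * cf['SERCA']:.1f}%  NCX {100 * cf['NCX']:.2f}%  "
      f"sarcolemmal Ca pump {100 * cf['pCa']:.2f}%")
print("(SERCA refills the SR; NCX and the pump extrude Ca from the cell)")
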