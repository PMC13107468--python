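# Externally computed SAPT0 component energies (kJ/mol) for slip-stacked
# acene dimers at fixed inter-planar distance dz = 3.4 A.
# Columns: system, dx, dy (A), E_int, E_el, E_ind, E_dsp, E_exch (kJ/mol).
system,dx,dy,E_int,E_el,E_ind,E_dsp,E_exch,position
Ben2,0.00,0.00,2.84,-14.86,-2.41,-42.09,62.21,cofacial
Ben2,1.57,0.90,-12.01,-10.11,-3.51,-31.10,32.71,slip-stacked
Ben2,1.74,0.00,-11.78,-10.49,-3.77,-31.81,34.29,x-stacked
Ben2,0.00,1.81,-12.01,-10.11,-3.51,-31.10,32.71,y-stacked
Nap2,0.00,0.00,-11.97,-25.07,-2.99,-79.82,95.91,cofacial
Nap2,1.35,0.99,-34.65,-19.53,-6.02,-66.72,57.62,slip-stacked
Nap2,1.46,0.00,-32.42,-21.53,-6.46,-71.45,67.02,x-stacked
Nap2,0.00,1.53,-31.22,-18.56,-5.12,-65.13,57.58,y-stacked
Ant2,0.00,0.00,-28.36,-35.44,-3.56,-119.80,130.43,cofacial
Ant2,1.31,1.00,-59.97,-28.78,-8.71,-104.12,81.63,slip-stacked
Ant2,1.37,0.00,-55.68,-32.06,-9.36,-112.53,98.27,x-stacked
Ant2,0.00,1.46,-53.29,-27.02,-6.43,-100.55,80.71,y-stacked
Tet2,0.00,0.00,-46.07,-45.89,-4.13,-161.18,165.13,cofacial
Tet2,1.28,1.00,-86.78,-38.08,-11.64,-142.96,105.90,slip-stacked
Tet2,1.33,0.00,-80.40,-42.40,-12.38,-154.64,129.02,x-stacked
Tet2,0.00,1.42,-76.83,-35.60,-7.72,-137.26,103.74,y-stacked
Pen2,0.00,0.00,-64.71,-56.44,-4.69,-203.57,200.00,cofacial
Pen2,1.27,1.01,-114.56,-47.30,-14.77,-182.22,129.72,slip-stacked
Pen2,1.31,0.00,-106.02,-52.71,-15.50,-197.48,159.68,x-stacked
Pen2,0.00,1.40,-101.40,-44.21,-9.06,-174.58,126.45,y-stacked
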