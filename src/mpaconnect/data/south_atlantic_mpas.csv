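id,name,lon,lat,area_km2,released_particles,n_cells
SPSP,Sao Pedro e Sao Paulo Archipelago,-29.3000,0.9000,125.62,213,4
ML,Parcel do Manuel Luis,-44.3333,0.9167,1257.68,530,16
FN,Fernando de Noronha Archipelago,-32.4833,-3.8500,447.24,247,8
AR,Atol das Rocas,-33.8000,-3.8500,308.72,123,4
RC,Recifes de Corais,-35.3000,-5.2167,1507.47,932,17
CC,Costa dos Corais,-35.2167,-9.2000,3995.42,1298,48
AB,Abrolhos,-38.6500,-17.9833,992.44,824,10
TR,Trindade e Martim Vaz Archipelago,-29.0667,-20.5000,2299.91,1221,24
CF,Arraial do Cabo e Cabo Frio,-41.1000,-22.8833,1616.67,692,23
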