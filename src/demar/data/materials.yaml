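# Material registry: maps material names to bundled attenuation tables or
# to elemental compositions (mass fractions).  Densities in g/cm^3.
# Dental-material compositions are documented surrogates for the real
# restorative/prosthetic specimens, which have unknown exact compositions.
basis: [water, iron]

tables:
  water:     {file: water.csv,    density: 1.00}
  gelatine:  {file: gelatine.csv, density: 1.02}   # gel ~ water attenuation, +2% density
  PLA:       {file: PLA.csv,      density: 1.25}
  iron:      {file: Fe.csv,       density: 7.874}
  hydrogen:  {file: H.csv,        density: 0.00008375}
  carbon:    {file: C.csv,        density: 2.0}
  nitrogen:  {file: N.csv,        density: 0.001165}
  oxygen:    {file: O.csv,        density: 0.001332}
  Al:        {file: Al.csv,       density: 2.699}
  Ca:        {file: Ca.csv,       density: 1.55}
  Ti:        {file: Ti.csv,       density: 4.506}
  Cr:        {file: Cr.csv,       density: 7.15}
  Co:        {file: Co.csv,       density: 8.86}
  Cu:        {file: Cu.csv,       density: 8.96}
  Zn:        {file: Zn.csv,       density: 7.134}
  Zr:        {file: Zr.csv,       density: 6.52}
  Mo:        {file: Mo.csv,       density: 10.22}
  Pd:        {file: Pd.csv,       density: 12.02}
  Ag:        {file: Ag.csv,       density: 10.49}
  Sn:        {file: Sn.csv,       density: 7.287}
  Au:        {file: Au.csv,       density: 19.30}
  Pt:        {file: Pt.csv,       density: 21.45}
  Hg:        {file: Hg.csv,       density: 13.534}

mixtures:
  titanium:        {composition: {Ti: 1.0}, density: 4.506}
  zirconia:        {composition: {Zr: 0.7403, oxygen: 0.2597}, density: 6.05}
  amalgam:         {composition: {Hg: 0.50, Ag: 0.30, Sn: 0.20}, density: 10.5}
  cobalt_chrome:   {composition: {Co: 0.60, Cr: 0.30, Mo: 0.10}, density: 8.3}
  high_gold:       {composition: {Au: 0.75, Pt: 0.15, Pd: 0.10}, density: 17.0}
  composite_resin: {composition: {carbon: 0.45, hydrogen: 0.05, oxygen: 0.30,
                                  Al: 0.08, Ca: 0.07, Zr: 0.05}, density: 2.0}
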