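# General chemistry scientific terms (IUPAC-compendium style subset).
concentration gradient
radial development
catalytic activity content
adsorption capacity
decomposition
activation energy
rate constant
reaction rate
reaction dynamics
reaction mechanism
osmotic pressure
solvation energy
surface tension
naphthenes
partial pressure
equilibrium constant
ionic strength
oxidation number
oxidation state
electron affinity
ionization energy
bond energy
bond order
dipole moment
electric dipole moment
molar mass
molar volume
mole fraction
mass fraction
vapour pressure
boiling point
melting point
critical temperature
critical pressure
phase transition
phase diagram
heat capacity
enthalpy of formation
enthalpy of reaction
gibbs energy
free energy
internal energy
entropy of reaction
chemical potential
chemical equilibrium
chemical kinetics
reaction order
rate law
rate determining step
elementary reaction
chain reaction
radical polymerization
polymerization
isomerization
hydrogenation
dehydrogenation
hydrolysis
electrolysis
photolysis
pyrolysis
oxidation
reduction
redox reaction
catalysis
heterogeneous catalysis
homogeneous catalysis
catalyst
catalytic activity
turnover frequency
turnover number
active site
surface coverage
adsorption isotherm
adsorption
desorption
chemisorption
physisorption
absorption coefficient
extinction coefficient
quantum yield
fluorescence
phosphorescence
luminescence
spectroscopy
mass spectrometry
nuclear magnetic resonance
electron paramagnetic resonance
infrared spectroscopy
x-ray diffraction
diffraction pattern
crystal structure
crystal lattice
lattice constant
unit cell
space group
point group
coordination number
coordination compound
ligand field
crystal field
band gap
fermi level
work function
electrode potential
standard electrode potential
electrochemical cell
fuel cell
galvanic cell
faraday constant
avogadro constant
boltzmann constant
gas constant
ideal gas
real gas
partition function
collision frequency
mean free path
diffusion coefficient
diffusion
thermal conductivity
viscosity
surface area
specific surface area
pore volume
pore size distribution
particle size
selectivity
conversion
yield
space velocity
residence time
mass transfer
heat transfer
transition state
activated complex
reaction intermediate
reaction coordinate
potential energy surface
isotope effect
kinetic isotope effect
isotopic labelling
buffer solution
acid dissociation constant
base dissociation constant
solubility product
common ion effect
hydrogen bond
covalent bond
ionic bond
metallic bond
van der waals forces
electronegativity
aromaticity
resonance structure
functional group
hydrocarbon
stoichiometry
stoichiometric coefficient
empirical formula
molecular formula
structural formula
molecular orbital
atomic orbital
valence electron
electron density
charge transfer
proton transfer
electron transfer
solvent effect
supercritical fluid
zeolite
mesoporous material
nanoparticle
monolayer
thin film
precursor
calcination
sintering
impregnation
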