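<Lems>
    <!-- Blocking + plastic synapse on a voltage-clamped test bed.  A
         regular 100 Hz spike train drives the synapse; the postsynaptic
         potential is held at +100 mV so the block mechanism is fully
         unblocked, and the short-term plasticity variables U and R shape
         the conductance across the train. -->

    <Include file="defs.xml"/>
    <Include file="basetypes.xml"/>
    <Include file="synapsetypes.xml"/>

    <ComponentType name="synapseTestBed">
        <Parameter name="vhold" dimension="voltage"/>
        <Exposure name="v" dimension="voltage"/>
        <Child name="synapse" type="baseSynapse"/>
        <Child name="spiker" type="baseSpikeSource"/>
        <Dynamics>
            <DerivedVariable name="v" dimension="voltage" exposure="v"
                             value="vhold"/>
        </Dynamics>
        <Structure>
            <EventConnection from="spiker" to="synapse"
                             sourcePort="spike" targetPort="in"/>
        </Structure>
    </ComponentType>

    <synapseTestBed id="bed" vhold="100 mV">
        <synapse type="blockingPlasticSynapse" gbase="1 nS" erev="0 mV"
                 tauRise="2 ms" tauDecay="10 ms">
            <blockMechanism type="voltageConcDepBlockMechanism"
                            blockConcentration="1 mM" scalingConc="3.57 mM"
                            scalingVolt="16.13 mV"/>
            <plasticityMechanism type="tsodyksMarkramDepFacMechanism"
                                 initReleaseProb="0.5" tauRec="120 ms"
                                 tauFac="10 ms"/>
        </synapse>
        <spiker type="spikeGenerator" period="10 ms" start="20 ms" stop="120 ms"/>
    </synapseTestBed>

    <Simulation id="sim" length="200 ms" step="0.05 ms" target="bed">
        <Display id="d0">
            <Line quantity="bed/synapse/g"/>
        </Display>
        <OutputFile id="of0" fileName="blocking_plastic_synapse.tsv">
            <OutputColumn quantity="bed/synapse/g"/>
            <OutputColumn quantity="bed/synapse/plasticityMechanism/U"/>
            <OutputColumn quantity="bed/synapse/plasticityMechanism/R"/>
        </OutputFile>
    </Simulation>

    <Target component="sim"/>
</Lems>
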