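<Lems>
    <!-- Ohmic (passive) channel on a single-compartment holder cell.
         The channel computes I = g (E - v) from the potential it reads
         from its enclosing scope; the cell integrates C dv/dt = I, so v
         relaxes exponentially to E with tau = C/g = 100 ms. -->

    <Include file="defs.xml"/>
    <Include file="basetypes.xml"/>
    <Include file="hhtypes.xml"/>

    <ComponentType name="passiveHolderCell" extends="baseCellMembPot">
        <Parameter name="C" dimension="capacitance"/>
        <Parameter name="v0" dimension="voltage"/>
        <Child name="channel" type="baseIonChannel"/>
        <Dynamics>
            <StateVariable name="v" dimension="voltage" exposure="v"/>
            <DerivedVariable name="iChan" dimension="current" select="channel/i"/>
            <TimeDerivative variable="v" value="iChan / C"/>
            <OnStart>
                <StateAssignment variable="v" value="v0"/>
            </OnStart>
        </Dynamics>
    </ComponentType>

    <passiveHolderCell id="cell" C="1 nF" v0="-55 mV">
        <channel type="passiveChannel" conductance="10 nS" erev="-65 mV"/>
    </passiveHolderCell>

    <Simulation id="sim" length="300 ms" step="0.1 ms" target="cell">
        <Display id="d0">
            <Line quantity="cell/v"/>
        </Display>
        <OutputFile id="of0" fileName="passive_channel.tsv">
            <OutputColumn quantity="cell/v"/>
            <OutputColumn quantity="cell/channel/i"/>
        </OutputFile>
    </Simulation>

    <Target component="sim"/>
</Lems>
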