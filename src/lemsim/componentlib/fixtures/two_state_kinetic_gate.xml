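<Lems>
    <!-- Two-state kinetic scheme with constant rates: closed <-> open with
         forward rate alpha = 2/ms and reverse rate beta = 1/ms, integrated
         as mean-field occupancy ODEs with conservation of total occupancy.
         The open fraction settles at alpha/(alpha+beta) = 2/3. -->

    <Include file="defs.xml"/>

    <ComponentType name="kineticState">
        <Exposure name="occupancy" dimension="none"/>
        <Dynamics>
            <StateVariable name="occupancy" dimension="none" exposure="occupancy"/>
        </Dynamics>
    </ComponentType>

    <ComponentType name="constantRateTransition">
        <Text name="from"/>
        <Text name="to"/>
        <Parameter name="forward" dimension="per_time"/>
        <Parameter name="reverse" dimension="per_time"/>
        <Exposure name="rf" dimension="per_time"/>
        <Exposure name="rr" dimension="per_time"/>
        <Dynamics>
            <DerivedVariable name="rf" dimension="per_time" exposure="rf"
                             value="forward"/>
            <DerivedVariable name="rr" dimension="per_time" exposure="rr"
                             value="reverse"/>
        </Dynamics>
    </ComponentType>

    <ComponentType name="twoStateGate">
        <Children name="states" type="kineticState"/>
        <Children name="transitions" type="constantRateTransition"/>
        <Exposure name="openFraction" dimension="none"/>
        <Dynamics>
            <DerivedVariable name="openFraction" dimension="none"
                             exposure="openFraction" select="o/occupancy"/>
            <KineticScheme name="ks" nodes="states" stateVariable="occupancy"
                           edges="transitions" edgeSource="from" edgeTarget="to"
                           forwardRate="rf" reverseRate="rr"/>
        </Dynamics>
    </ComponentType>

    <twoStateGate id="gate">
        <kineticState id="c"/>
        <kineticState id="o"/>
        <constantRateTransition id="t1" from="c" to="o"
                                forward="2 per_ms" reverse="1 per_ms"/>
    </twoStateGate>

    <Simulation id="sim" length="50 ms" step="0.01 ms" target="gate">
        <Display id="d0">
            <Line quantity="gate/openFraction"/>
        </Display>
        <OutputFile id="of0" fileName="two_state_kinetic_gate.tsv">
            <OutputColumn quantity="gate/c/occupancy"/>
            <OutputColumn quantity="gate/o/occupancy"/>
            <OutputColumn quantity="gate/openFraction"/>
        </OutputFile>
    </Simulation>

    <Target component="sim"/>
</Lems>
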