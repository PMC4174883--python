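<Lems>
    <!-- Three-cell mutually inhibitory ring built from the adaptive
         exponential cell and the blocking plastic synapse, echoing the
         classic pyloric-network topology.  Each cell receives the same
         step-current drive; spikes travel around the ring through
         dynamically attached inhibitory synapses with 5 ms delay. -->

    <Include file="defs.xml"/>
    <Include file="basetypes.xml"/>
    <Include file="adextypes.xml"/>
    <Include file="synapsetypes.xml"/>
    <Include file="networktypes.xml"/>

    <adExCell id="cell" C="281 pF" gL="30 nS" EL="-70.6 mV" VT="-50.4 mV"
              delT="2 mV" Vr="-70.6 mV" a="4 nS" b="80.5 pA" tauw="144 ms"
              refract="2 ms" threshold="-40 mV">
        <input type="pulseGenerator" delay="20 ms" duration="160 ms"
               amplitude="0.8 nA"/>
    </adExCell>

    <blockingPlasticSynapse id="syn" gbase="5 nS" erev="-80 mV"
                            tauRise="1 ms" tauDecay="8 ms">
        <blockMechanism type="voltageConcDepBlockMechanism"
                        blockConcentration="0 mM" scalingConc="3.57 mM"
                        scalingVolt="16.13 mV"/>
        <plasticityMechanism type="tsodyksMarkramDepFacMechanism"
                             initReleaseProb="0.5" tauRec="120 ms"
                             tauFac="10 ms"/>
    </blockingPlasticSynapse>

    <network id="net">
        <population id="pop" size="3" component="cell"/>
        <synapticConnection id="c01" from="pop/cell[0]" to="pop/cell[1]"
                            delay="5 ms" weight="1" synapse="syn"/>
        <synapticConnection id="c12" from="pop/cell[1]" to="pop/cell[2]"
                            delay="5 ms" weight="1" synapse="syn"/>
        <synapticConnection id="c20" from="pop/cell[2]" to="pop/cell[0]"
                            delay="5 ms" weight="1" synapse="syn"/>
    </network>

    <Simulation id="sim" length="200 ms" step="0.05 ms" target="net">
        <Display id="d0">
            <Line quantity="pop/cell[0]/v"/>
            <Line quantity="pop/cell[1]/v"/>
            <Line quantity="pop/cell[2]/v"/>
        </Display>
        <OutputFile id="of0" fileName="small_network.tsv">
            <OutputColumn quantity="pop/cell[0]/v"/>
            <OutputColumn quantity="pop/cell[1]/v"/>
            <OutputColumn quantity="pop/cell[2]/v"/>
        </OutputFile>
    </Simulation>

    <Target component="sim"/>
</Lems>
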